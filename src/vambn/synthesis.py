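"""End-to-end pipeline: module autoencoders -> Bayesian network -> cohorts.

`train` splits the cohort into its variable modules, trains one autoencoder
per module (or per module and visit for the baseline variant), assembles the
embedding table together with standalone covariates and visit-attendance
indicators, and fits the constrained Bayesian network over it.  `generate`
draws synthetic embeddings from the network and decodes them; raw output has
full attendance and no cell-level missingness.  `post_process` then matches a
reference cohort's participant count, attendance patterns and sex fraction,
and drops study-time values beyond the reference's observed maximum.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_data import CohortTable, VariableSpec, VisitMap, build_missingness_indicators
from .hivae import Hivae, HivaeConfig, ModuleEncoding, fit_module
from .mbn import BayesNet, EdgeConstraints, assemble_bn_inputs, fit_parameters, learn_structure, sample_embeddings

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "Generator", "train", "generate", "post_process", "sample_study"]


@dataclass(frozen=True)
class PipelineConfig:
    """Study-level settings for training and sampling."""

    variant: str = "MT"  # "baseline" | "FT" | "MT"
    hivae: HivaeConfig = field(default_factory=HivaeConfig)
    module_overrides: Mapping[str, HivaeConfig] = field(default_factory=dict)
    constraints: EdgeConstraints = field(default_factory=EdgeConstraints)
    exclude_covariates: tuple[str, ...] = ("fam_id",)  # identifier-like statics
    bn_max_parents: int = 4
    bn_restarts: int = 3
    sample_size: int = 1312
    post_process: bool = True
    oversample_factor: float = 1.5  # raw pool size relative to sample_size
    n_datasets: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_datasets < 1 or self.sample_size < 1:
            raise ValueError("n_datasets and sample_size must be >= 1")
        if self.variant not in ("baseline", "FT", "MT"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class Generator:
    """Self-contained trained artefact: module autoencoders plus the network."""

    variant: str
    specs: list[VariableSpec]
    visit_map: VisitMap
    models: dict  # module -> Hivae (FT/MT) or (module, visit) -> Hivae (baseline)
    net: BayesNet
    covariates: list[str]
    discrete_covariates: list[str]
    id_name: str = "pers_id"

    @property
    def module_names(self) -> list[str]:
        mods = {s.module for s in self.specs if s.role == "longitudinal"}
        return sorted(mods)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "Generator":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _module_config(config: PipelineConfig, module: str, variant: str) -> HivaeConfig:
    base = config.module_overrides.get(module, config.hivae)
    tag = sum(ord(c) for c in module) % 1000  # stable across processes
    return replace(base, variant=variant, seed=base.seed + tag)


def _node_groups(generator_or_models, variant: str):
    """Module-node labels as they appear in the BN table."""
    if variant == "baseline":
        return sorted({f"{m}v{v:02d}" for (m, v) in generator_or_models})
    return sorted(generator_or_models)


def _auto_constraints(
    groups: list[str], z_dim_of: Mapping[str, int], variant: str,
    user: EdgeConstraints,
) -> EdgeConstraints:
    """Merge user lists with the structural defaults.

    Every module's component node is whitelisted into its own code nodes; for
    the baseline variant, edges from later-visit module nodes back to
    earlier-visit ones are blacklisted (time's arrow).
    """
    white = set(user.whitelist)
    for g in groups:
        for k in range(z_dim_of[g]):
            white.add((f"{g}_s", f"{g}_z{k}"))
    black = set(user.blacklist)
    if variant == "baseline":
        def visit_of(g):
            return int(g[-2:])

        def nodes_of(g):
            return [f"{g}_s"] + [f"{g}_z{k}" for k in range(z_dim_of[g])]

        for g1 in groups:
            for g2 in groups:
                if visit_of(g1) < visit_of(g2):
                    for a in nodes_of(g2):
                        for b in nodes_of(g1):
                            black.add((a, b))
    return EdgeConstraints(blacklist=frozenset(black - white), whitelist=frozenset(white))


def train(cohort: CohortTable, config: PipelineConfig) -> Generator:
    """Train all module autoencoders and the Bayesian network over them."""
    variant = config.variant
    modules = sorted({s.module for s in cohort.longitudinal_specs if s.module})
    models: dict = {}
    encodings: dict[str, ModuleEncoding] = {}

    for mod in modules:
        values, mask, specs = cohort.module_slice(mod)
        cfg = _module_config(config, mod, variant)
        try:
            if variant in ("FT", "MT"):
                model, enc = fit_module(values, mask, specs, cfg)
                models[mod] = model
                encodings[mod] = enc
            else:
                for v in range(cohort.n_visits):
                    vcfg = replace(cfg, seed=cfg.seed + v)
                    model, enc = fit_module(
                        values[:, v : v + 1, :], mask[:, v : v + 1, :], specs, vcfg
                    )
                    models[(mod, v)] = model
                    encodings[f"{mod}v{v:02d}"] = enc
        except Exception as exc:
            raise RuntimeError(f"module {mod!r} failed to train: {exc}") from exc

    indicators = build_missingness_indicators(cohort)
    cov_names = [
        s.name for s in cohort.static_specs if s.name not in config.exclude_covariates
    ]
    discrete_cov = [
        s.name for s in cohort.static_specs
        if s.name in cov_names and s.is_discrete
    ]
    covariates = cohort.static[cov_names] if cov_names else None

    table, discrete = assemble_bn_inputs(
        encodings, cohort.ids, covariates, discrete_cov, indicators
    )
    groups = sorted(encodings)
    z_dim_of = {g: encodings[g].z.shape[1] for g in groups}
    constraints = _auto_constraints(groups, z_dim_of, variant, config.constraints)

    structure = learn_structure(
        table, constraints, seed=config.seed, discrete=discrete,
        max_parents=config.bn_max_parents, n_restarts=config.bn_restarts,
    )
    net = fit_parameters(structure, table)

    return Generator(
        variant=variant,
        specs=list(cohort.specs),
        visit_map=cohort.visit_map,
        models=models,
        net=net,
        covariates=cov_names,
        discrete_covariates=discrete_cov,
        id_name=cohort.id_name,
    )


def generate(generator: Generator, n: int, seed: int = 0) -> CohortTable:
    """Decode `n` synthetic participants; full attendance, no missing cells."""
    if n < 0:
        raise ValueError("n must be non-negative")
    vm = generator.visit_map
    V = vm.n_visits
    long_specs = [s for s in generator.specs if s.role == "longitudinal"]
    names = [s.name for s in long_specs]
    D = len(names)
    rng = np.random.default_rng(seed)

    table = sample_embeddings(generator.net, n, seed=seed)
    values = np.empty((n, V, D))

    def block_slots(specs):
        return [names.index(s.name) for s in specs]

    if generator.variant in ("FT", "MT"):
        for mod, model in sorted(generator.models.items()):
            s = table[f"{mod}_s"].to_numpy(dtype=int)
            z = np.column_stack([
                table[f"{mod}_z{k}"].to_numpy(dtype=float)
                for k in range(model.config.z_dim)
            ]) if n else np.empty((0, model.config.z_dim))
            enc = ModuleEncoding(s=s, z=z, q_s=np.eye(model.config.s_dim)[s] if n else np.empty((0, model.config.s_dim)))
            block = model.sample_cells(enc, rng) if n else np.empty((0, V, len(model.specs)))
            values[:, :, block_slots(model.specs)] = block
    else:
        for (mod, v), model in sorted(generator.models.items()):
            g = f"{mod}v{v:02d}"
            s = table[f"{g}_s"].to_numpy(dtype=int)
            z = np.column_stack([
                table[f"{g}_z{k}"].to_numpy(dtype=float)
                for k in range(model.config.z_dim)
            ]) if n else np.empty((0, model.config.z_dim))
            enc = ModuleEncoding(s=s, z=z, q_s=np.eye(model.config.s_dim)[s] if n else np.empty((0, model.config.s_dim)))
            block = model.sample_cells(enc, rng) if n else np.empty((0, 1, len(model.specs)))
            values[:, v : v + 1, block_slots(model.specs)] = block

    ids = pd.Index([f"S{i + 1:06d}" for i in range(n)], name=generator.id_name)
    static_cols = {}
    for s in generator.specs:
        if s.role != "static":
            continue
        if s.name in generator.covariates:
            static_cols[s.name] = table[s.name].to_numpy()
        else:
            static_cols[s.name] = np.arange(1, n + 1, dtype=float)  # fresh identifiers
    static = pd.DataFrame(static_cols, index=ids)

    return CohortTable(
        specs=list(generator.specs),
        static=static,
        values=values,
        mask=np.ones((n, V, D), dtype=bool),
        attendance=np.ones((n, V), dtype=bool),
        visit_map=vm,
        id_name=generator.id_name,
    )


def post_process(
    raw: CohortTable,
    reference: CohortTable,
    seed: int = 0,
    sex_var: str = "sex",
    time_var: str = "time",
) -> CohortTable:
    """Match the reference's size, sex fraction and attendance pattern.

    Participants are chosen from the raw pool by stratified subsampling on
    sex; each kept participant receives an attendance pattern resampled from
    the reference's empirical patterns (non-attended visits are blanked), and
    study-time values beyond the reference's observed maximum blank their
    visit.  Blanking only removes values; surviving cells are untouched.
    """
    n_ref = reference.n_participants
    if raw.n_participants < n_ref:
        raise ValueError(
            f"raw cohort ({raw.n_participants}) smaller than reference ({n_ref})"
        )
    rng = np.random.default_rng(seed)

    if sex_var in raw.static.columns and sex_var in reference.static.columns:
        ref_sex = reference.static[sex_var].to_numpy()
        raw_sex = raw.static[sex_var].to_numpy()
        chosen: list[int] = []
        for level in np.unique(ref_sex):
            need = int((ref_sex == level).sum())
            pool = np.flatnonzero(raw_sex == level)
            if len(pool) < need:
                raise ValueError(
                    f"raw pool has {len(pool)} participants with {sex_var}={level}, "
                    f"needs {need}; increase the oversampling factor"
                )
            chosen.extend(rng.choice(pool, size=need, replace=False).tolist())
        keep = np.sort(np.asarray(chosen))
    else:
        keep = np.sort(rng.choice(raw.n_participants, size=n_ref, replace=False))

    values = raw.values[keep].copy()
    mask = raw.mask[keep].copy()
    static = raw.static.iloc[keep].copy()

    pattern_rows = rng.integers(0, n_ref, size=n_ref)
    attendance = reference.attendance[pattern_rows].copy()

    if time_var in raw.long_var_names:
        d = raw.var_index(time_var)
        tmax = np.nanmax(reference.variable(time_var))
        future = np.nan_to_num(values[:, :, d], nan=-np.inf) > tmax
        attendance &= ~future

    return CohortTable(
        specs=list(raw.specs),
        static=static,
        values=values,
        mask=mask,
        attendance=attendance,
        visit_map=raw.visit_map,
        id_name=raw.id_name,
    )


def sample_study(
    generator: Generator,
    reference: CohortTable | None,
    config: PipelineConfig,
) -> list[CohortTable]:
    """Draw `n_datasets` cohorts from one model with per-dataset derived seeds."""
    out = []
    for i in range(config.n_datasets):
        seed_i = config.seed + 1000 + i
        if config.post_process:
            if reference is None:
                raise ValueError("post-processing requires a reference cohort")
            n_raw = max(
                int(np.ceil(config.sample_size * config.oversample_factor)),
                config.sample_size + 1,
            )
            raw = generate(generator, n_raw, seed=seed_i)
            out.append(post_process(raw, reference, seed=seed_i))
        else:
            out.append(generate(generator, config.sample_size, seed=seed_i))
    return out
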