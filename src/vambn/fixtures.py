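"""Ground-truth cohort simulator.

Emulates the structure of an annual nutrition cohort following children from
age 3 to 18: one row per attended visit, a mix of statistical types, whole
skipped visits, and three deterministic dependencies that a faithful
generative model must respect:

* ``time`` (study age) and ``alter`` (participant age) are locked —
  ``time = alter + offset`` with a fixed per-participant birth offset;
* a maternal-education flag that can flip 0 -> 1 but never back;
* protein / fat / carbohydrate energy fractions summing to exactly 100.

The added-sugar outcome ``zuzu_p`` carries a cubic age trend plus a cubic
calendar-time trend with per-participant random intercepts, so the simulator
doubles as the parameter-recovery oracle for the mixed-model trend analysis.
All coefficients are returned alongside the data as the ground-truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_data import CohortTable, VariableSpec, VisitMap

__all__ = ["FixtureConfig", "generate_fixture", "corrupt_fixture", "small_fixture_config"]


@dataclass(frozen=True)
class FixtureConfig:
    """Simulator parameters; defaults mirror the emulated study's shape."""

    n_participants: int = 1312
    n_visits: int = 16
    base_age: int = 3
    study_span: float = 30.0  # calendar years covered by the study
    late_entry_prob: float = 0.3  # minority of participants enter after visit 0
    max_entry_visit: int = 6
    skip_prob: float = 0.1  # per-visit skip probability after entry
    sex_fraction: float = 0.52  # fraction of girls
    # added sugar (%E): intercept + cubic(age) + cubic(time) + u_i + eps
    sugar_intercept: float = 13.0
    age_coefs: tuple[float, float, float] = (-0.35, 0.21, -0.012)
    time_coefs: tuple[float, float, float] = (-0.2, 0.008, -0.0001)
    intercept_sd: float = 2.0
    residual_sd: float = 2.0
    education_start_prob: float = 0.3
    education_flip_prob: float = 0.05  # per-visit 0 -> 1 probability
    education_missing_rate: float = 0.0017
    overweight_missing_rate: float = 0.0125
    modules: tuple[str, ...] = ("T", "N", "A", "S")
    n_filler: int = 22  # persistent AR(1) filler variables -> 33 longitudinal total
    filler_rho: float = 0.8
    seed: int = 12345

    def __post_init__(self):
        if self.n_visits < 2:
            raise ValueError("n_visits >= 2 required")
        for p in (self.late_entry_prob, self.skip_prob, self.sex_fraction,
                  self.education_start_prob, self.education_flip_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def small_fixture_config(
    n_participants: int = 300,
    n_visits: int = 4,
    n_filler: int = 2,
    seed: int = 7,
    **overrides,
) -> FixtureConfig:
    """A compact two-module cohort (times + socioeconomic, 6 variables).

    Strong cross-visit structure (the time/age lock, the monotone flag and
    persistent filler tracks) makes it a sharp probe for how well a generator
    preserves longitudinal dependencies.
    """
    return FixtureConfig(
        n_participants=n_participants,
        n_visits=n_visits,
        modules=("T", "S"),
        n_filler=n_filler,
        skip_prob=overrides.pop("skip_prob", 0.05),
        late_entry_prob=overrides.pop("late_entry_prob", 0.1),
        max_entry_visit=min(2, n_visits - 2),
        education_missing_rate=0.0,
        overweight_missing_rate=0.0,
        seed=seed,
        **overrides,
    )


def _cubic(x: np.ndarray, coefs: Sequence[float]) -> np.ndarray:
    c1, c2, c3 = coefs
    return c1 * x + c2 * x**2 + c3 * x**3


def _build_specs(cfg: FixtureConfig) -> list[VariableSpec]:
    specs: list[VariableSpec] = [
        VariableSpec("fam_id", "count", "static"),
        VariableSpec("sex", "boolean", "static"),
    ]
    core = {
        "T": [VariableSpec("alter", "positive_real", module="T"),
              VariableSpec("time", "positive_real", module="T")],
        "N": [VariableSpec("zuzu_p", "positive_real", module="N"),
              VariableSpec("zuck_p", "positive_real", module="N"),
              VariableSpec("EW_p", "positive_real", module="N"),
              VariableSpec("Fett_p", "positive_real", module="N"),
              VariableSpec("KH_p", "positive_real", module="N")],
        "A": [VariableSpec("height", "real", module="A"),
              VariableSpec("weight", "positive_real", module="A")],
        "S": [VariableSpec("m_schulab", "boolean", module="S"),
              VariableSpec("m_ovw", "boolean", module="S")],
    }
    for m in cfg.modules:
        specs.extend(core[m])
    filler_homes = [m for m in cfg.modules if m != "T"] or list(cfg.modules)
    for k in range(cfg.n_filler):
        home = filler_homes[k % len(filler_homes)]
        specs.append(VariableSpec(f"x{k + 1:02d}", "real", module=home))
    return specs


def generate_fixture(cfg: FixtureConfig) -> tuple[CohortTable, dict]:
    """Simulate one cohort; returns the table plus the ground-truth record."""
    rng = np.random.default_rng(cfg.seed)
    n, V = cfg.n_participants, cfg.n_visits
    vm = VisitMap(base_age=cfg.base_age, n_visits=V)
    specs = _build_specs(cfg)
    long_specs = [s for s in specs if s.role == "longitudinal"]
    names = [s.name for s in long_specs]
    D = len(names)

    # attendance: entry visit, then independent per-visit skips
    top_entry = max(min(cfg.max_entry_visit, V - 1), 1)
    entry = np.where(
        rng.random(n) < cfg.late_entry_prob,
        rng.integers(1, top_entry + 1, size=n),
        0,
    )
    attendance = np.arange(V)[None, :] >= entry[:, None]
    attendance &= rng.random((n, V)) >= cfg.skip_prob
    # every participant attends at least one visit: force the entry visit
    attendance[np.arange(n), entry] = True

    sex = (rng.random(n) < cfg.sex_fraction).astype(float)  # 1 = girl
    fam_id = rng.permutation(n) + 1000

    ages = cfg.base_age + np.arange(V)[None, :] + rng.uniform(-0.25, 0.25, (n, V))
    offsets = rng.uniform(
        1.0 - cfg.base_age, cfg.study_span - cfg.base_age - V + 1.0, size=n
    )
    times = ages + offsets[:, None]

    intercepts = rng.normal(0.0, cfg.intercept_sd, size=n)
    zuzu = (
        cfg.sugar_intercept
        + _cubic(ages, cfg.age_coefs)
        + _cubic(times, cfg.time_coefs)
        + intercepts[:, None]
        + rng.normal(0.0, cfg.residual_sd, (n, V))
    )
    zuzu = np.clip(zuzu, 0.1, None)
    zuck = zuzu + np.abs(rng.normal(8.0, 2.0, (n, V)))

    # macronutrients on the simplex, scaled so the triple sums to exactly 100
    frac = rng.dirichlet([13.0 * 1.5, 34.0 * 1.5, 53.0 * 1.5], size=(n, V))
    ew = 100.0 * frac[:, :, 0]
    fett = 100.0 * frac[:, :, 1]
    kh = 100.0 - ew - fett

    height = (
        70.0 + 6.2 * ages - 0.08 * ages**2
        + rng.normal(0.0, 4.0, n)[:, None] + rng.normal(0.0, 1.5, (n, V))
    )
    weight = np.exp(
        2.3 + 0.11 * ages - 0.0017 * ages**2
        + rng.normal(0.0, 0.12, n)[:, None] + rng.normal(0.0, 0.05, (n, V))
    )

    edu0 = (rng.random(n) < cfg.education_start_prob).astype(float)
    edu = np.empty((n, V))
    edu[:, 0] = edu0
    for v in range(1, V):
        flip = rng.random(n) < cfg.education_flip_prob
        edu[:, v] = np.maximum(edu[:, v - 1], flip.astype(float))
    ovw = np.repeat((rng.random(n) < 0.35).astype(float)[:, None], V, axis=1)

    columns = {
        "alter": ages, "time": times, "zuzu_p": zuzu, "zuck_p": zuck,
        "EW_p": ew, "Fett_p": fett, "KH_p": kh,
        "height": height, "weight": weight, "m_schulab": edu, "m_ovw": ovw,
    }
    for k in range(cfg.n_filler):
        mu = rng.normal(0.0, 2.0)
        level = rng.normal(mu, 1.0, size=n)
        track = np.empty((n, V))
        track[:, 0] = level + rng.normal(0.0, 0.5, n)
        for v in range(1, V):
            track[:, v] = (
                level + cfg.filler_rho * (track[:, v - 1] - level)
                + rng.normal(0.0, 0.5, n)
            )
        columns[f"x{k + 1:02d}"] = track

    values = np.stack([columns[name] for name in names], axis=2)
    mask = np.repeat(attendance[:, :, None], D, axis=2)

    # sprinkle the two documented low-level cell missingness patterns
    for var, rate in (("m_schulab", cfg.education_missing_rate),
                      ("m_ovw", cfg.overweight_missing_rate)):
        if var in names and rate > 0:
            d = names.index(var)
            holes = (rng.random((n, V)) < rate) & attendance
            mask[:, :, d] &= ~holes

    ids = pd.Index([f"P{i + 1:05d}" for i in range(n)], name="pers_id")
    static = pd.DataFrame({"fam_id": fam_id.astype(float), "sex": sex}, index=ids)
    cohort = CohortTable(
        specs=specs, static=static, values=values, mask=mask,
        attendance=attendance, visit_map=vm,
    )
    truth = {
        "config": asdict(cfg),
        "sugar_intercept": cfg.sugar_intercept,
        "age_coefs": list(cfg.age_coefs),
        "time_coefs": list(cfg.time_coefs),
        "intercept_sd": cfg.intercept_sd,
        "residual_sd": cfg.residual_sd,
        "offsets": offsets.tolist(),
        "intercepts": intercepts.tolist(),
        "entry_visits": entry.tolist(),
    }
    return cohort, truth


# ---------------------------------------------------------------------------
# negative controls
# ---------------------------------------------------------------------------


def corrupt_fixture(
    cohort: CohortTable,
    mode: str,
    magnitude: float = 1.0,
    n_inject: int = 1,
    seed: int = 0,
) -> tuple[CohortTable, list[dict]]:
    """Inject a known number of dependency violations; returns the ledger.

    Modes: ``monotone`` flips an education value 1 -> 0 between two attended
    visits; ``time_jitter`` shifts one ``time`` value by ``magnitude`` at an
    interior attended visit (producing a +magnitude / -magnitude error pair);
    ``composition`` adds ``magnitude`` to one protein cell.  Injection sites
    are kept two observed positions apart so each entry contributes exactly
    its ledgered defect and nothing else.
    """
    if mode not in ("monotone", "time_jitter", "composition"):
        raise ValueError(f"unknown corruption mode {mode!r}")
    out = cohort.copy()
    ledger: list[dict] = []
    if magnitude == 0 or n_inject == 0:
        return out, ledger
    rng = np.random.default_rng(seed)

    var = {"monotone": "m_schulab", "time_jitter": "time", "composition": "EW_p"}[mode]
    d = out.var_index(var)
    track = out.values[:, :, d]
    obs = out.mask[:, :, d]

    candidates: list[tuple[int, int]] = []  # (participant, observed-position)
    obs_visits: dict[int, np.ndarray] = {}
    for i in range(out.n_participants):
        vis = np.flatnonzero(obs[i])
        obs_visits[i] = vis
        if mode == "monotone":
            for t in range(len(vis) - 1):
                if track[i, vis[t]] == 1.0 and track[i, vis[t + 1]] == 1.0:
                    candidates.append((i, t))
        elif mode == "time_jitter":
            for t in range(1, len(vis) - 1):
                candidates.append((i, t))
        else:
            for t in range(len(vis)):
                candidates.append((i, t))

    rng.shuffle(candidates)
    taken: dict[int, list[int]] = {}
    for i, t in candidates:
        if len(ledger) == n_inject:
            break
        if any(abs(t - u) < 2 for u in taken.get(i, [])):
            continue
        taken.setdefault(i, []).append(t)
        vis = obs_visits[i]
        if mode == "monotone":
            v = vis[t + 1]
            track[i, v] = 0.0
            ledger.append({"participant": int(i), "visit": int(v), "kind": "monotone_flip"})
        elif mode == "time_jitter":
            v = vis[t]
            track[i, v] += magnitude
            ledger.append({"participant": int(i), "visit": int(v),
                           "kind": "time_jitter", "magnitude": float(magnitude)})
        else:
            v = vis[t]
            track[i, v] += magnitude
            ledger.append({"participant": int(i), "visit": int(v),
                           "kind": "composition_shift", "magnitude": float(magnitude)})
    if len(ledger) < n_inject:
        raise ValueError(f"could not place {n_inject} injections (got {len(ledger)})")
    return out, ledger
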