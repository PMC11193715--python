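"""Four-level quality evaluation of synthetic cohorts.

1. *Individual distributions*: per-variable summary statistics and the
   Jensen-Shannon divergence (base 2, so values lie in [0, 1]) between real
   and synthetic samples, binned with shared edges chosen as the larger of
   Sturges' and the Freedman-Diaconis bin counts; discrete variables use raw
   category frequencies.
2. *Correlation structure*: Pearson matrices over all (variable, visit)
   columns (pairwise-complete) and the relative error
   eps = ||R_real - R_synth||_F / ||R_real||_F.
3. *Direct dependencies*: monotone-flag violation rate, the per-visit-pair
   time-minus-age increment error, and the macronutrient composition error
   |protein + fat + carbohydrate - 100|.
4. *Real-world trend analysis*: cubic polynomial mixed-effects regressions
   (random intercept per participant, ML fit) of an outcome against age or
   study time, aggregated over many sampled datasets into mean curves,
   2.5%/97.5% quantile bands and the fraction of datasets in which all three
   polynomial terms are significant at p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .cohort_data import CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "BinningRule",
    "EvalReport",
    "summary_stats",
    "bin_edges",
    "js_divergence",
    "ordered_columns",
    "correlation_matrix",
    "relative_frobenius",
    "correlation_error",
    "impose_missingness",
    "monotone_violation_rate",
    "delta_consistency_error",
    "composition_error",
    "trend_fit",
    "trend_aggregate",
    "evaluate_cohorts",
    "plot_correlation_heatmaps",
    "plot_trend_band",
]


# ---------------------------------------------------------------------------
# level 1: distributions
# ---------------------------------------------------------------------------


def summary_stats(values) -> dict:
    """Mean, SD, median and quartiles of the observed (non-NaN) values."""
    x = np.asarray(values, dtype=float).ravel()
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("summary_stats: no observed values")
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "median": float(np.median(x)),
        "q25": float(np.quantile(x, 0.25)),
        "q75": float(np.quantile(x, 0.75)),
        "n": int(x.size),
    }


@dataclass(frozen=True)
class BinningRule:
    """Shared histogram edges applied to both compared samples."""

    edges: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1


def _sturges_bins(n: int) -> int:
    return int(np.ceil(np.log2(n))) + 1 if n > 1 else 1


def _fd_bins(x: np.ndarray, span: float) -> int:
    iqr = float(np.quantile(x, 0.75) - np.quantile(x, 0.25))
    width = 2.0 * iqr * len(x) ** (-1.0 / 3.0)
    if width <= 0 or span <= 0:
        return 1
    return int(np.ceil(span / width))


def bin_edges(reference_values, pooled_range: tuple[float, float] | None = None) -> BinningRule:
    """Choose the bin count as max(Sturges, Freedman-Diaconis) on the reference.

    Edges are equally spaced across `pooled_range` (by default the reference's
    own range) so the same rule can be applied to both samples.  A constant
    reference degenerates to a single bin.
    """
    x = np.asarray(reference_values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    lo, hi = pooled_range if pooled_range is not None else (x.min(), x.max())
    if x.size < 2 or np.unique(x).size < 2 or hi <= lo:
        center = float(x[0]) if x.size else 0.0
        lo = min(lo, center) if hi > lo else center - 0.5
        hi = max(hi, center) if hi > lo else center + 0.5
        return BinningRule(edges=np.array([lo, hi]))
    n_bins = max(_sturges_bins(x.size), _fd_bins(x, hi - lo))
    return BinningRule(edges=np.linspace(lo, hi, n_bins + 1))


def js_divergence(real_values, synthetic_values, rule: BinningRule | None = None,
                  discrete: bool = False) -> float:
    """Base-2 Jensen-Shannon divergence of the two binned probability vectors."""
    x = np.asarray(real_values, dtype=float).ravel()
    y = np.asarray(synthetic_values, dtype=float).ravel()
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("js_divergence: empty sample")
    if discrete:
        levels = np.union1d(np.unique(x), np.unique(y))
        p = np.array([(x == lvl).sum() for lvl in levels], dtype=float)
        q = np.array([(y == lvl).sum() for lvl in levels], dtype=float)
    else:
        if rule is None:
            lo = float(min(x.min(), y.min()))
            hi = float(max(x.max(), y.max()))
            rule = bin_edges(x, pooled_range=(lo, hi))
        edges = rule.edges
        p, _ = np.histogram(np.clip(x, edges[0], edges[-1]), bins=edges)
        q, _ = np.histogram(np.clip(y, edges[0], edges[-1]), bins=edges)
    p = p / p.sum()
    q = q / q.sum()
    return float(jensenshannon(p, q, base=2) ** 2)


# ---------------------------------------------------------------------------
# level 2: correlation structure
# ---------------------------------------------------------------------------


def ordered_columns(cohort: CohortTable) -> list[tuple[str, int]]:
    """(variable, visit) pairs, module-group-major then visit-ascending."""
    groups: dict[str | None, list[str]] = {}
    for s in cohort.longitudinal_specs:
        groups.setdefault(s.module, []).append(s.name)
    cols = []
    for mod in sorted(groups, key=lambda m: (m is None, str(m))):
        for name in sorted(groups[mod]):
            for v in range(cohort.n_visits):
                cols.append((name, v))
    return cols


def correlation_matrix(cohort: CohortTable) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of all longitudinal columns."""
    cols = ordered_columns(cohort)
    data = {
        f"{name}_VIS{v:02d}": cohort.variable(name)[:, v] for name, v in cols
    }
    frame = pd.DataFrame(data, index=cohort.ids)
    return frame.corr(method="pearson", min_periods=2)


def relative_frobenius(real_matrix, synthetic_matrix) -> float:
    """||R_real - R_synth||_F / ||R_real||_F with undefined entries as zero."""
    rm = np.nan_to_num(np.asarray(real_matrix, dtype=float), nan=0.0)
    sm = np.nan_to_num(np.asarray(synthetic_matrix, dtype=float), nan=0.0)
    return float(np.linalg.norm(rm - sm) / np.linalg.norm(rm))


def correlation_error(real: CohortTable, synthetic: CohortTable) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Pearson matrices of both cohorts and the relative Frobenius error.

    Both cohorts must share the (variable, visit) column set; the synthetic
    cohort should already carry reference-matched missingness (see
    `impose_missingness`).  Undefined correlations (constant columns) count
    as zero in both matrices.
    """
    if set(real.long_var_names) != set(synthetic.long_var_names) or (
        real.n_visits != synthetic.n_visits
    ):
        raise ValueError("cohorts do not share the (variable, visit) column set")
    r = correlation_matrix(real)
    s = correlation_matrix(synthetic)
    s = s.reindex(index=r.index, columns=r.columns)
    eps = relative_frobenius(r.to_numpy(), s.to_numpy())
    return r, s, eps


def impose_missingness(synthetic: CohortTable, reference: CohortTable) -> CohortTable:
    """Copy the reference's attendance and cell mask onto the synthetic cohort."""
    if synthetic.n_participants != reference.n_participants:
        raise ValueError("cohorts must have equal size to transfer the mask")
    out = synthetic.copy()
    out.attendance = reference.attendance.copy()
    out.mask = synthetic.mask & reference.mask.copy()
    out.values = np.where(out.mask, out.values, np.nan)
    return out


# ---------------------------------------------------------------------------
# level 3: direct dependencies
# ---------------------------------------------------------------------------


def monotone_violation_rate(trajectories: np.ndarray, observed: np.ndarray) -> tuple[float, np.ndarray]:
    """Rate of observed consecutive (1, 0) transitions of a boolean flag.

    Transitions are taken between successive *observed* entries of each
    trajectory.  Returns the overall rate and the per-trajectory counts.
    """
    traj = np.asarray(trajectories, dtype=float)
    obs = np.asarray(observed, dtype=bool)
    n = traj.shape[0]
    counts = np.zeros(n, dtype=int)
    total_transitions = 0
    for i in range(n):
        seq = traj[i, obs[i]]
        if len(seq) < 2:
            continue
        total_transitions += len(seq) - 1
        counts[i] = int(np.sum((seq[:-1] == 1.0) & (seq[1:] == 0.0)))
    rate = counts.sum() / total_transitions if total_transitions else 0.0
    return float(rate), counts


def delta_consistency_error(age_track: np.ndarray, time_track: np.ndarray,
                            observed: np.ndarray) -> np.ndarray:
    """Delta(time) - Delta(age) over consecutive observed visit pairs.

    In data respecting the age/time lock every entry is exactly zero; with
    full attendance over V visits each participant contributes V - 1 errors.
    """
    age = np.asarray(age_track, dtype=float)
    tim = np.asarray(time_track, dtype=float)
    obs = np.asarray(observed, dtype=bool) & ~np.isnan(age) & ~np.isnan(tim)
    errors: list[float] = []
    for i in range(age.shape[0]):
        vis = np.flatnonzero(obs[i])
        if len(vis) < 2:
            continue
        d_time = np.diff(tim[i, vis])
        d_age = np.diff(age[i, vis])
        errors.extend((d_time - d_age).tolist())
    return np.asarray(errors)


def composition_error(protein: np.ndarray, fat: np.ndarray, carbohydrate: np.ndarray,
                      observed: np.ndarray | None = None) -> np.ndarray:
    """|protein + fat + carbohydrate - 100| per jointly observed record."""
    p = np.asarray(protein, dtype=float)
    f = np.asarray(fat, dtype=float)
    c = np.asarray(carbohydrate, dtype=float)
    total = p + f + c
    ok = ~np.isnan(total)
    if observed is not None:
        ok &= np.asarray(observed, dtype=bool)
    return np.abs(total[ok] - 100.0)


# ---------------------------------------------------------------------------
# level 4: trend analysis
# ---------------------------------------------------------------------------


def trend_fit(
    long_table: pd.DataFrame,
    outcome: str,
    axis: str,
    group_col: str = "pers_id",
    grid: np.ndarray | None = None,
) -> dict:
    """Cubic mixed-effects trend: outcome ~ axis + axis^2 + axis^3 + (1|id).

    Maximum-likelihood fit with a per-participant random intercept. Returns
    fixed effects, Wald p-values of the three polynomial terms, the fitted
    population curve on `grid`, and a convergence flag.
    """
    from scipy.special import comb
    from scipy.stats import norm
    from statsmodels.regression.mixed_linear_model import MixedLM

    df = long_table[[group_col, axis, outcome]].dropna()
    x = df[axis].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 50)
    # fit on a centred/scaled axis (raw cubic designs are ill-conditioned),
    # then map coefficients and covariance back to the raw basis exactly
    c, s = float(x.mean()), float(max(x.std(), 1e-12))
    u = (x - c) / s
    exog = np.column_stack([np.ones_like(u), u, u**2, u**3])
    A = np.zeros((4, 4))  # raw_coefs = A @ scaled_coefs
    for k in range(4):
        for j in range(k + 1):
            A[j, k] = comb(k, j) * (-c) ** (k - j) / s**k
    converged = True
    try:
        import warnings

        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(y, exog, groups=df[group_col].to_numpy())
            for method in ("lbfgs", "bfgs", "powell"):
                try:
                    res = model.fit(reml=False, method=method, maxiter=500, disp=False)
                    break
                except np.linalg.LinAlgError:
                    continue
        if res is None:
            raise np.linalg.LinAlgError("all optimisers failed")
        converged = bool(getattr(res, "converged", True))
        coefs = A @ np.asarray(res.fe_params)
        cov = A @ np.asarray(res.cov_params())[:4, :4] @ A.T
        se = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
        zstat = coefs / se
        pvals = 2.0 * norm.sf(np.abs(zstat))[1:4]
        stderr = se
    except Exception as exc:  # noqa: BLE001 - flagged, not fatal
        logger.warning("trend_fit failed: %s", exc)
        converged = False
        coefs = np.full(4, np.nan)
        pvals = np.full(3, np.nan)
        stderr = np.full(4, np.nan)
    curve = coefs[0] + coefs[1] * grid + coefs[2] * grid**2 + coefs[3] * grid**3
    return {
        "coefs": coefs,
        "stderr": stderr,
        "pvalues": pvals,
        "grid": np.asarray(grid),
        "curve": curve,
        "converged": converged,
        "n_obs": int(len(df)),
    }


def trend_aggregate(fits: list[dict], alpha: float = 0.05) -> dict:
    """Mean curve, empirical 2.5%/97.5% bands and joint-significance fraction."""
    good = [f for f in fits if f["converged"] and np.all(np.isfinite(f["coefs"]))]
    dropped = len(fits) - len(good)
    if dropped:
        logger.warning("trend_aggregate: excluding %d non-converged fits", dropped)
    if len(good) < 2:
        raise ValueError("need at least 2 successful fits to aggregate")
    curves = np.stack([f["curve"] for f in good])
    sig = np.array([np.all(f["pvalues"] < alpha) for f in good])
    return {
        "grid": good[0]["grid"],
        "mean_curve": curves.mean(axis=0),
        "q025": np.quantile(curves, 0.025, axis=0),
        "q975": np.quantile(curves, 0.975, axis=0),
        "significant_fraction": float(sig.mean()),
        "n_fits": len(good),
        "n_excluded": dropped,
        "coefs": np.stack([f["coefs"] for f in good]),
    }


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Bundle of the four metric levels comparing synthetic to reference."""

    per_variable: pd.DataFrame
    js_mean: float
    js_sd: float
    correlation_eps: float
    dependencies: dict = field(default_factory=dict)
    trends: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        import json

        doc = {
            "per_variable": self.per_variable.to_dict(orient="records"),
            "js_mean": self.js_mean,
            "js_sd": self.js_sd,
            "correlation_eps": self.correlation_eps,
            "dependencies": {
                k: (float(v) if np.isscalar(v) else np.asarray(v).tolist())
                for k, v in self.dependencies.items()
            },
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def plot_correlation_heatmaps(real_matrix: pd.DataFrame, synth_matrix: pd.DataFrame,
                              path, eps: float | None = None) -> None:
    """Side-by-side Pearson heatmaps (PNG/SVG decided by the file suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 5))
    for ax, mat, title in zip(axes, (real_matrix, synth_matrix), ("reference", "synthetic")):
        im = ax.imshow(np.nan_to_num(mat.to_numpy(), nan=0.0), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_title(title)
        ax.set_xticks([])
        ax.set_yticks([])
    if eps is not None:
        fig.suptitle(f"relative correlation error = {eps:.3f}")
    fig.colorbar(im, ax=axes, shrink=0.8)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_trend_band(aggregate: dict, path, reference_fit: dict | None = None,
                    xlabel: str = "age [years]", ylabel: str = "outcome") -> None:
    """Mean synthetic trend with its 2.5%/97.5% band, optionally vs reference."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    g = aggregate["grid"]
    ax.fill_between(g, aggregate["q025"], aggregate["q975"], alpha=0.3,
                    label="2.5%-97.5% band")
    ax.plot(g, aggregate["mean_curve"], label="synthetic mean")
    if reference_fit is not None:
        ax.plot(reference_fit["grid"], reference_fit["curve"], "r--", label="reference")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def evaluate_cohorts(real: CohortTable, synthetic: CohortTable,
                     match_missingness: bool = True) -> EvalReport:
    """Levels 1-3 of the evaluation for one synthetic cohort."""
    synth = synthetic
    if match_missingness and synthetic.n_participants == real.n_participants:
        synth = impose_missingness(synthetic, real)

    rows = []
    js_values = []
    for spec in real.longitudinal_specs:
        rx = real.variable(spec.name)
        sx = synth.variable(spec.name)
        if np.all(np.isnan(sx)) or np.all(np.isnan(rx)):
            continue
        stats_r = summary_stats(rx[~np.isnan(rx)])
        stats_s = summary_stats(sx[~np.isnan(sx)])
        per_visit = []
        for v in range(real.n_visits):
            a, b = rx[:, v], sx[:, v]
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            if a.size == 0 or b.size == 0:
                continue
            per_visit.append(js_divergence(a, b, discrete=spec.is_discrete))
        js = float(np.mean(per_visit)) if per_visit else np.nan
        js_values.append(js)
        rows.append({
            "variable": spec.name,
            **{f"real_{k}": v for k, v in stats_r.items()},
            **{f"synth_{k}": v for k, v in stats_s.items()},
            "js_divergence": js,
        })
    per_variable = pd.DataFrame(rows)

    _, _, eps = correlation_error(real, synth)

    deps = {}
    names = set(real.long_var_names)
    if "m_schulab" in names:
        d = real.var_index("m_schulab")
        rate, _ = monotone_violation_rate(
            synth.values[:, :, synth.var_index("m_schulab")],
            synth.mask[:, :, synth.var_index("m_schulab")],
        )
        deps["monotone_violation_rate"] = rate
        rate_real, _ = monotone_violation_rate(real.values[:, :, d], real.mask[:, :, d])
        deps["monotone_violation_rate_real"] = rate_real
    if {"alter", "time"} <= names:
        err = delta_consistency_error(
            synth.variable("alter"), synth.variable("time"),
            synth.attendance,
        )
        deps["delta_errors_mean_abs"] = float(np.mean(np.abs(err))) if err.size else 0.0
    if {"EW_p", "Fett_p", "KH_p"} <= names:
        comp = composition_error(
            synth.variable("EW_p"), synth.variable("Fett_p"), synth.variable("KH_p")
        )
        deps["composition_error_mean"] = float(np.mean(comp)) if comp.size else 0.0

    return EvalReport(
        per_variable=per_variable,
        js_mean=float(np.nanmean(js_values)) if js_values else np.nan,
        js_sd=float(np.nanstd(js_values)) if js_values else np.nan,
        correlation_eps=eps,
        dependencies=deps,
    )
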