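"""Metric layer: binning, divergence, correlation error, dependencies, trends."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vambn import (
    bin_edges,
    composition_error,
    correlation_error,
    delta_consistency_error,
    generate_fixture,
    js_divergence,
    monotone_violation_rate,
    small_fixture_config,
    summary_stats,
    trend_aggregate,
    trend_fit,
)
from vambn.evaluation import relative_frobenius


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def test_summary_stats_examples():
    s = summary_stats([1, 2, 3, 4, 5])
    assert s["mean"] == 3 and s["median"] == 3
    assert summary_stats([7.0] * 10)["sd"] == 0.0
    with pytest.raises(ValueError):
        summary_stats([np.nan])


def test_summary_stats_matches_textbook_formulas():
    rng = np.random.default_rng(0)
    x = rng.gamma(2.0, 1.5, size=501)
    s = summary_stats(x)
    n = len(x)
    mean = x.sum() / n
    sd = np.sqrt(((x - mean) ** 2).sum() / (n - 1))
    assert abs(s["mean"] - mean) < 1e-12
    assert abs(s["sd"] - sd) < 1e-12
    assert abs(s["median"] - np.sort(x)[n // 2]) < 1e-12


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def test_constant_reference_degenerates_to_single_bin():
    rule = bin_edges(np.full(100, 3.2))
    assert rule.n_bins == 1


def test_sturges_count_at_1024():
    rng = np.random.default_rng(1)
    x = rng.normal(size=1024)
    rule = bin_edges(x)
    sturges = int(np.ceil(np.log2(1024))) + 1
    assert sturges == 11
    iqr = np.quantile(x, 0.75) - np.quantile(x, 0.25)
    fd = int(np.ceil((x.max() - x.min()) / (2 * iqr * 1024 ** (-1 / 3))))
    assert rule.n_bins == max(11, fd)


def test_heavy_tailed_sample_lets_fd_win():
    rng = np.random.default_rng(2)
    x = rng.standard_cauchy(1000)
    rule = bin_edges(x)
    sturges = int(np.ceil(np.log2(1000))) + 1
    assert rule.n_bins > sturges


# ---------------------------------------------------------------------------
# JS divergence
# ---------------------------------------------------------------------------


def test_js_identical_samples_zero():
    x = np.random.default_rng(3).normal(size=500)
    assert js_divergence(x, x) == pytest.approx(0.0, abs=1e-12)


def test_js_disjoint_support_is_one():
    assert js_divergence(np.zeros(50), np.ones(50), discrete=True) == pytest.approx(1.0)


def test_js_half_half_versus_point_mass():
    # freq vectors (0.5, 0.5) vs (1, 0); hand-evaluated base-2 JS divergence
    real = np.array([0.0, 1.0])
    synth = np.array([0.0, 0.0])
    expected = 0.5 * (0.5 * np.log2(0.5 / 0.75) + 0.5 * np.log2(0.5 / 0.25)) + 0.5 * np.log2(
        1 / 0.75
    )
    assert js_divergence(real, synth, discrete=True) == pytest.approx(expected, abs=1e-9)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_js_symmetric_and_bounded(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, 200)
    y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), 200)
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    rule = bin_edges(x, pooled_range=(lo, hi))
    a = js_divergence(x, y, rule)
    b = js_divergence(y, x, rule)
    assert a == pytest.approx(b, abs=1e-12)
    assert 0.0 <= a <= 1.0


# ---------------------------------------------------------------------------
# correlation error
# ---------------------------------------------------------------------------


def test_identical_cohorts_zero_error(small_cohort):
    cohort, _, _ = small_cohort
    _, _, eps = correlation_error(cohort, cohort)
    assert eps == pytest.approx(0.0, abs=1e-12)


def test_hand_evaluated_frobenius_ratio():
    r = np.array([[1.0, 0.5], [0.5, 1.0]])
    s = np.eye(2)
    assert relative_frobenius(r, s) == pytest.approx(np.sqrt(0.5) / np.sqrt(2.5), abs=1e-12)
    assert relative_frobenius(r, np.zeros((2, 2))) == pytest.approx(1.0, abs=1e-12)


def test_epsilon_scale_free():
    rng = np.random.default_rng(4)
    a = rng.normal(size=(5, 5))
    b = rng.normal(size=(5, 5))
    assert relative_frobenius(a, b) == pytest.approx(relative_frobenius(3.7 * a, 3.7 * b))


def test_column_mismatch_rejected(small_cohort):
    cohort, _, _ = small_cohort
    other, _ = generate_fixture(small_fixture_config(n_participants=20, n_visits=5, seed=1))
    with pytest.raises(ValueError):
        correlation_error(cohort, other)


# ---------------------------------------------------------------------------
# direct dependencies
# ---------------------------------------------------------------------------


def test_monotone_examples():
    rate, counts = monotone_violation_rate(
        np.array([[0, 0, 1, 1]]), np.ones((1, 4), bool)
    )
    assert rate == 0.0 and counts.tolist() == [0]
    rate, counts = monotone_violation_rate(np.array([[1, 0]]), np.ones((1, 2), bool))
    assert rate == 1.0 and counts.tolist() == [1]


def test_monotone_rate_equals_bruteforce_on_random_batch():
    rng = np.random.default_rng(5)
    traj = rng.integers(0, 2, (100, 8)).astype(float)
    obs = rng.random((100, 8)) > 0.3
    rate, counts = monotone_violation_rate(traj, obs)
    viol = trans = 0
    for i in range(100):
        seq = [traj[i, v] for v in range(8) if obs[i, v]]
        for a, b in zip(seq[:-1], seq[1:]):
            trans += 1
            viol += (a == 1.0) and (b == 0.0)
    assert counts.sum() == viol
    assert rate == pytest.approx(viol / trans)


def test_delta_errors_count_and_perfect_lock():
    n, V = 30, 16
    rng = np.random.default_rng(6)
    age = np.cumsum(rng.uniform(0.8, 1.2, (n, V)), axis=1)
    time = age + rng.uniform(0, 20, (n, 1))
    err = delta_consistency_error(age, time, np.ones((n, V), bool))
    assert err.shape == (n * (V - 1),)  # 15 per fully attended participant
    assert np.allclose(err, 0.0, atol=1e-12)


def test_delta_error_single_jitter_pattern():
    age = np.tile(np.arange(5, dtype=float), (1, 1))
    time = age + 3.0
    time[0, 2] += 0.5
    err = delta_consistency_error(age, time, np.ones((1, 5), bool))
    assert np.allclose(err, [0.0, 0.5, -0.5, 0.0])


def test_composition_examples():
    assert composition_error([13.0], [34.0], [53.0])[0] == pytest.approx(0.0)
    assert composition_error([15.0], [40.0], [55.0])[0] == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# trends
# ---------------------------------------------------------------------------


def _cubic_long(coefs, n=150, V=8, ri_sd=0.0, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    ages = np.tile(np.linspace(3, 17, V), (n, 1))
    b0, b1, b2, b3 = coefs
    y = b0 + b1 * ages + b2 * ages**2 + b3 * ages**3
    y += rng.normal(0, ri_sd, (n, 1)) + rng.normal(0, noise_sd, (n, V))
    return pd.DataFrame({
        "pers_id": np.repeat(np.arange(n), V),
        "age": ages.ravel(),
        "y": y.ravel(),
    })


def test_noise_free_cubic_recovered_exactly():
    coefs = (2.0, -0.5, 0.3, -0.01)
    fit = trend_fit(_cubic_long(coefs), "y", "age")
    assert fit["converged"]
    assert np.allclose(fit["coefs"], coefs, atol=1e-5)


def test_constant_outcome_not_significant():
    long = _cubic_long((5.0, 0.0, 0.0, 0.0), noise_sd=1.0, seed=1)
    fit = trend_fit(long, "y", "age")
    assert np.all(np.abs(fit["coefs"][1:]) < 0.1)
    assert not np.all(fit["pvalues"] < 0.05)


def test_trend_aggregate_bands_and_significance():
    fits = [
        trend_fit(_cubic_long((2.0, -0.5, 0.3, -0.01), noise_sd=0.5, ri_sd=0.5, seed=s),
                  "y", "age", grid=np.linspace(3, 17, 10))
        for s in range(6)
    ]
    agg = trend_aggregate(fits)
    curves = np.stack([f["curve"] for f in fits if f["converged"]])
    # sort-based quantile oracle
    oracle_lo = np.quantile(np.sort(curves, axis=0), 0.025, axis=0)
    assert np.allclose(agg["q025"], oracle_lo)
    assert np.all(agg["q025"] <= agg["mean_curve"] + 1e-12)
    assert np.all(agg["mean_curve"] <= agg["q975"] + 1e-12)
    assert agg["significant_fraction"] == 1.0

    same = trend_aggregate([fits[0], fits[0]])
    assert np.allclose(same["q025"], same["q975"])


def test_plot_helpers_write_files(tmp_path, small_cohort):
    from vambn.evaluation import (correlation_matrix, plot_correlation_heatmaps,
                                  plot_trend_band)

    cohort, _, _ = small_cohort
    mat = correlation_matrix(cohort)
    heat = tmp_path / "corr.png"
    plot_correlation_heatmaps(mat, mat, heat, eps=0.0)
    assert heat.stat().st_size > 0

    fits = [trend_fit(_cubic_long((2.0, -0.5, 0.3, -0.01), noise_sd=0.5, seed=s),
                      "y", "age", grid=np.linspace(3, 17, 8)) for s in range(2)]
    agg = trend_aggregate(fits)
    band = tmp_path / "trend.svg"
    plot_trend_band(agg, band, reference_fit=fits[0])
    assert band.stat().st_size > 0
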