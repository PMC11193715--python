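"""Autoencoder: autodiff gradients, typed likelihood heads, masking, variants."""

import numpy as np
import pytest

from vambn import VariableSpec
from vambn._nn import Adam, Dense, Tensor, concat, constant
from vambn.hivae import Hivae, HivaeConfig, SchemaError, fit_module

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# autodiff core
# ---------------------------------------------------------------------------


def test_gradients_match_finite_differences():
    rng = np.random.default_rng(0)
    W1, W2 = rng.normal(size=(4, 3)), rng.normal(size=(3, 2))
    x = rng.normal(size=(5, 4))

    def loss_value(w1, w2):
        h = np.tanh(x @ w1)
        p = np.exp(h @ w2)
        return float(np.sum(np.log(1.0 + p)))

    tw1, tw2 = Tensor(W1.copy()), Tensor(W2.copy())
    h = (constant(x) @ tw1).tanh()
    loss = (1.0 + (h @ tw2).exp()).log().sum()
    loss.backward()

    eps = 1e-6
    for tensor, w in ((tw1, W1), (tw2, W2)):
        num = np.zeros_like(w)
        for idx in np.ndindex(w.shape):
            wp, wm = w.copy(), w.copy()
            wp[idx] += eps
            wm[idx] -= eps
            if w is W1:
                num[idx] = (loss_value(wp, W2) - loss_value(wm, W2)) / (2 * eps)
            else:
                num[idx] = (loss_value(W1, wp) - loss_value(W1, wm)) / (2 * eps)
        assert np.allclose(tensor.grad, num, atol=1e-6)


def test_softmax_concat_slicing_gradients():
    rng = np.random.default_rng(1)
    a = Tensor(rng.normal(size=(3, 4)))
    b = Tensor(rng.normal(size=(3, 2)))
    out = concat([a.log_softmax(axis=1).exp(), b.sigmoid()], axis=1)
    loss = (out[:, 1:4] ** 2.0).sum()
    loss.backward()
    assert a.grad is not None and b.grad is not None
    assert a.grad.shape == a.data.shape

    # numeric check on one entry of a
    def f(adata):
        sa = np.exp(adata - adata.max(1, keepdims=True))
        sa = sa / sa.sum(1, keepdims=True)
        sb = 1 / (1 + np.exp(-b.data))
        o = np.concatenate([sa, sb], axis=1)
        return float(np.sum(o[:, 1:4] ** 2))

    eps = 1e-6
    ap, am = a.data.copy(), a.data.copy()
    ap[0, 0] += eps
    am[0, 0] -= eps
    assert np.isclose(a.grad[0, 0], (f(ap) - f(am)) / (2 * eps), atol=1e-6)


# ---------------------------------------------------------------------------
# module fitting
# ---------------------------------------------------------------------------

_ALL_TYPES = [
    VariableSpec("r", "real", module="M"),
    VariableSpec("p", "positive_real", module="M"),
    VariableSpec("c", "count", module="M"),
    VariableSpec("k", "categorical", module="M", n_categories=3),
    VariableSpec("b", "boolean", module="M"),
    VariableSpec("o", "ordinal", module="M", n_categories=4),
]


def _mixed_batch(n=60, V=2, seed=0):
    rng = np.random.default_rng(seed)
    vals = np.stack(
        [
            rng.normal(0, 1, (n, V)),
            np.exp(rng.normal(0, 0.5, (n, V))),
            rng.poisson(4.0, (n, V)).astype(float),
            rng.integers(0, 3, (n, V)).astype(float),
            rng.integers(0, 2, (n, V)).astype(float),
            rng.integers(0, 4, (n, V)).astype(float),
        ],
        axis=2,
    )
    mask = rng.random((n, V, 6)) > 0.15
    return vals, mask


def test_sampled_values_respect_declared_domains():
    vals, mask = _mixed_batch(seed=1)
    cfg = HivaeConfig(variant="FT", epochs=15, seed=2)
    model, enc = fit_module(vals, mask, _ALL_TYPES, cfg)
    draw = model.sample_cells(enc, np.random.default_rng(5))
    assert (draw[:, :, 1] > 0).all()  # positive_real
    counts = draw[:, :, 2]
    assert (counts >= 0).all() and np.allclose(counts, np.round(counts))
    assert set(np.unique(draw[:, :, 3])) <= {0.0, 1.0, 2.0}
    assert set(np.unique(draw[:, :, 4])) <= {0.0, 1.0}
    assert set(np.unique(draw[:, :, 5])) <= {0.0, 1.0, 2.0, 3.0}


def test_categorical_head_probabilities_normalised(trained_mt):
    model, enc, values, mask = trained_mt
    params = model.decoder_params(enc)
    for v in range(model.V):
        for d, spec in enumerate(model.specs):
            if spec.is_discrete:
                p = params[v][d]["probs"]
                assert np.allclose(p.sum(axis=1), 1.0)
                assert (p >= 0).all()


def test_decoder_head_count_is_visits_times_variables(trained_mt):
    model, enc, _, _ = trained_mt
    params = model.decoder_params(enc)
    assert len(params) == model.V
    assert sum(len(row) for row in params) == model.V * len(model.specs)


def test_mt_yields_one_encoding_per_participant(trained_mt):
    model, enc, values, _ = trained_mt
    assert enc.z.shape == (values.shape[0], model.config.z_dim)
    assert enc.s.shape == (values.shape[0],)
    assert np.allclose(enc.s_onehot.sum(axis=1), 1.0)


def test_masked_input_value_never_changes_loss(trained_mt):
    model, _, values, mask = trained_mt
    assert not mask.all()
    v2 = values.copy()
    i, v, d = np.argwhere(~mask)[0]
    v2[i, v, d] = 1e6
    rng_a = np.random.default_rng(0)
    rng_b = np.random.default_rng(0)
    la = model._loss(np.where(mask, values, np.nan), mask, rng_a)
    lb = model._loss(np.where(mask, v2, np.nan), mask, rng_b)
    assert float(la.data) == float(lb.data)


def test_seeded_training_is_bitwise_reproducible():
    vals, mask = _mixed_batch(n=40, seed=3)
    cfg = HivaeConfig(variant="MT", epochs=8, seed=9)
    _, enc1 = fit_module(vals, mask, _ALL_TYPES, cfg)
    _, enc2 = fit_module(vals, mask, _ALL_TYPES, cfg)
    assert np.array_equal(enc1.z, enc2.z)
    assert np.array_equal(enc1.s, enc2.s)


def test_schema_mismatch_rejected(trained_mt):
    model, _, values, mask = trained_mt
    with pytest.raises(SchemaError):
        model.encode(values[:, :, :1], mask[:, :, :1])


@pytest.mark.parametrize("variant", ["baseline", "FT", "MT"])
def test_variants_share_contract_at_single_visit(variant):
    vals, mask = _mixed_batch(n=40, V=1, seed=4)
    cfg = HivaeConfig(variant=variant, epochs=5, seed=1)
    model, enc = fit_module(vals, mask, _ALL_TYPES, cfg)
    assert enc.z.shape == (40, cfg.z_dim)
    draw = model.sample_cells(enc, np.random.default_rng(0))
    assert draw.shape == (40, 1, 6)


def test_baseline_requires_single_visit():
    with pytest.raises(ValueError):
        Hivae(_ALL_TYPES, n_visits=2, config=HivaeConfig(variant="baseline"))


def test_constant_variable_is_reconstructed():
    rng = np.random.default_rng(0)
    n = 60
    vals = np.stack([np.full((n, 1), 5.0), rng.normal(0, 1, (n, 1))], axis=2)
    mask = np.ones((n, 1, 2), bool)
    specs = [VariableSpec("const", "real", module="M"),
             VariableSpec("noise", "real", module="M")]
    model, enc = fit_module(vals, mask, specs, HivaeConfig(variant="FT", epochs=60, seed=0))
    recon = model.sample_cells(enc, np.random.default_rng(1))
    assert abs(recon[:, 0, 0].mean() - 5.0) < 0.2


def test_nan_in_observed_cell_rejected(trained_mt):
    model, _, values, mask = trained_mt
    bad = values.copy()
    i, v, d = np.argwhere(mask)[0]
    bad[i, v, d] = np.nan
    with pytest.raises(ValueError):
        model.elbo(bad, mask)


def test_single_gaussian_cell_unit_variance_loglik():
    """A zero-residual unit-variance Gaussian head scores -log(2*pi)/2."""
    spec = VariableSpec("r", "real", module="M")
    n = 4
    vals = np.zeros((n, 1, 1))
    mask = np.ones((n, 1, 1), bool)
    model = Hivae([spec], n_visits=1, config=HivaeConfig(variant="FT", epochs=1, seed=0))
    model._build(vals, mask)
    head = model.heads[0][0]
    head.logvar.data[:] = 0.0  # unit variance
    params = {"kind": "real", "mu": np.zeros(n), "logvar": 0.0}
    ll = head.np_loglik(params, np.full(n, head.codec.m))  # residual 0 on std scale
    assert np.allclose(ll, -0.5 * _LOG2PI)
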