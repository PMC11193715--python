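"""Heterogeneous-incomplete variational autoencoder for one variable module.

The latent is a Gaussian mixture: a categorical component ``s`` (one-hot,
uniform prior) selects the mean of ``p(z|s)``; a shared network ``g(z)``
produces a homogeneous representation ``Y`` (one slice per visit), and a
separate small head parameterises the likelihood of every (visit, variable)
cell, with a type-specific distribution per declared dtype:

====================  ====================================================
dtype                 likelihood head
====================  ====================================================
real                  Gaussian on the standardised scale
positive_real         Gaussian on the standardised log scale (log-normal)
count                 Poisson with log-link
categorical/boolean   softmax over levels
ordinal               cumulative-link (ordered thresholds minus a scalar)
====================  ====================================================

The ELBO sums log-likelihood contributions over *observed* cells only;
missing inputs are zero-filled after standardisation and contribute nothing.
Three encoder variants share this decoder: ``baseline`` sees a single visit,
``FT`` flattens all visits into one feedforward input, and ``MT`` runs the
per-visit inputs through an LSTM whose final state summarises the sequence.
The expectation over the discrete component is taken by exact enumeration
(weighted by q(s|x)), which keeps training gradients low-variance without a
relaxation of the one-hot sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from ._nn import LSTM, Adam, Dense, Tensor, concat, constant
from .cohort_data import VariableSpec

__all__ = ["HivaeConfig", "ModuleEncoding", "Hivae", "fit_module"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class HivaeConfig:
    """Architecture and training hyperparameters for one module."""

    variant: str = "MT"  # "baseline" | "FT" | "MT"
    s_dim: int = 3
    z_dim: int = 2
    hidden_dim: int = 32
    lstm_units: int = 16  # LSTM output dimensionality h_end (MT only)
    y_dim: int = 8  # width of each visit's slice of Y
    epochs: int = 250
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.variant not in ("baseline", "FT", "MT"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.s_dim < 1 or self.z_dim < 1:
            raise ValueError("s_dim and z_dim must be >= 1")


@dataclass
class ModuleEncoding:
    """Posterior-mode embedding of one participant batch for one module."""

    s: np.ndarray  # (N,) component indices
    z: np.ndarray  # (N, z_dim)
    q_s: np.ndarray  # (N, s_dim) posterior component probabilities

    @property
    def s_onehot(self) -> np.ndarray:
        k = self.q_s.shape[1]
        return np.eye(k)[self.s]


class SchemaError(ValueError):
    pass


class TrainingDivergedError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# per-variable feature codecs
# ---------------------------------------------------------------------------


class _Codec:
    """Transform one variable to encoder features and score its likelihood."""

    def __init__(self, spec: VariableSpec, observed: np.ndarray):
        self.spec = spec
        self.kind = spec.dtype
        if self.kind in ("real", "positive_real", "count"):
            y = observed
            if self.kind == "positive_real":
                y = np.log(np.maximum(observed, 1e-10))
            elif self.kind == "count":
                y = np.log1p(observed)
            self.m = float(np.mean(y)) if y.size else 0.0
            self.s = float(max(np.std(y), 1e-6)) if y.size else 1.0
            self.n_enc = 1
            self.n_out = 1
        else:
            self.K = int(spec.n_categories)
            self.n_enc = self.K if self.kind != "ordinal" else self.K - 1
            self.n_out = self.K if self.kind != "ordinal" else 1

    # encoder-side feature (filled value for missing is all-zero)
    def enc_features(self, x: np.ndarray, obs: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        if self.kind in ("real", "positive_real", "count"):
            y = x.copy()
            if self.kind == "positive_real":
                y = np.log(np.maximum(np.nan_to_num(y, nan=1.0), 1e-10))
            elif self.kind == "count":
                y = np.log1p(np.nan_to_num(y, nan=0.0))
            z = (np.nan_to_num(y, nan=self.m) - self.m) / self.s
            return np.where(obs, z, 0.0)[:, None]
        codes = np.nan_to_num(x, nan=0.0).astype(int)
        codes = np.clip(codes, 0, self.K - 1)
        if self.kind == "ordinal":
            thermo = (np.arange(1, self.K)[None, :] <= codes[:, None]).astype(float)
            return np.where(obs[:, None], thermo, 0.0)
        onehot = np.zeros((n, self.K))
        onehot[np.arange(n), codes] = 1.0
        return np.where(obs[:, None], onehot, 0.0)

    def target(self, x: np.ndarray) -> np.ndarray:
        """Value on the likelihood's own scale (standardised / codes / counts)."""
        if self.kind in ("real", "positive_real"):
            y = np.nan_to_num(x, nan=self.m)
            if self.kind == "positive_real":
                y = np.log(np.maximum(np.nan_to_num(x, nan=1.0), 1e-10))
            return (y - self.m) / self.s
        if self.kind == "count":
            return np.nan_to_num(x, nan=0.0)
        return np.clip(np.nan_to_num(x, nan=0.0).astype(int), 0, self.K - 1)


class _Head:
    """Likelihood head of one (visit, variable) cell."""

    def __init__(self, codec: _Codec, n_in: int, rng: np.random.Generator):
        self.codec = codec
        self.dense = Dense(n_in, codec.n_out, rng)
        self.extra: list[Tensor] = []
        if codec.kind in ("real", "positive_real"):
            self.logvar = Tensor(np.zeros(1))
            self.extra = [self.logvar]
        elif codec.kind == "ordinal":
            self.raw_thresh = Tensor(np.linspace(-1.0, 1.0, codec.K - 1))
            self.extra = [self.raw_thresh]

    @property
    def params(self):
        return self.dense.params + self.extra

    # ---- differentiable per-cell log-likelihood, masked ------------------
    def loglik(self, inp: Tensor, x: np.ndarray, obs: np.ndarray) -> Tensor:
        """(N,) tensor of log-likelihoods; masked-out cells contribute 0."""
        m = constant(obs.astype(float))
        out = self.dense(inp)
        kind = self.codec.kind
        if kind in ("real", "positive_real"):
            xt = constant(self.codec.target(x))
            mu = out.reshape(-1)
            lv = self.logvar[0]
            ll = (
                constant(-0.5 * _LOG2PI)
                + lv * -0.5
                + (xt - mu) ** 2.0 * (lv * -1.0).exp() * -0.5
            )
        elif kind == "count":
            xt = self.codec.target(x)
            a = out.reshape(-1)
            lam = a.exp()
            ll = constant(xt) * a - lam - constant(gammaln(xt + 1.0))
        elif kind == "ordinal":
            probs = self._ordinal_probs(out)
            onehot = np.eye(self.codec.K)[self.codec.target(x)]
            ll = ((probs + 1e-10).log() * constant(onehot)).sum(axis=1)
        else:  # categorical / boolean
            logp = out.log_softmax(axis=1)
            onehot = np.eye(self.codec.K)[self.codec.target(x)]
            ll = (logp * constant(onehot)).sum(axis=1)
        return ll * m

    def _ordinal_probs(self, out: Tensor) -> Tensor:
        thresh = self.raw_thresh.softplus().cumsum()  # ordered, positive gaps
        h = out  # (N, 1)
        cdf = (thresh.reshape(1, -1) - h).sigmoid()  # (N, K-1)
        first = cdf[:, 0:1]
        mids = cdf[:, 1:] - cdf[:, :-1] if self.codec.K > 2 else None
        last = 1.0 - cdf[:, -1:]
        pieces = [first] + ([mids] if mids is not None else []) + [last]
        return concat(pieces, axis=1)

    # ---- numpy parameter extraction and sampling --------------------------
    def np_params(self, inp: np.ndarray) -> dict:
        out = inp @ self.dense.W.data + self.dense.b.data
        kind = self.codec.kind
        if kind in ("real", "positive_real"):
            return {"kind": kind, "mu": out[:, 0], "logvar": float(self.logvar.data[0])}
        if kind == "count":
            return {"kind": kind, "log_rate": out[:, 0]}
        if kind == "ordinal":
            thresh = np.cumsum(np.logaddexp(0.0, self.raw_thresh.data))
            cdf = 1.0 / (1.0 + np.exp(-(thresh[None, :] - out)))
            probs = np.diff(np.concatenate(
                [np.zeros((len(out), 1)), cdf, np.ones((len(out), 1))], axis=1), axis=1)
            return {"kind": kind, "probs": probs}
        shifted = out - out.max(axis=1, keepdims=True)
        p = np.exp(shifted)
        return {"kind": kind, "probs": p / p.sum(axis=1, keepdims=True)}

    def np_loglik(self, params: dict, x: np.ndarray) -> np.ndarray:
        kind = self.codec.kind
        if kind in ("real", "positive_real"):
            xt = self.codec.target(x)
            lv = params["logvar"]
            return -0.5 * _LOG2PI - 0.5 * lv - 0.5 * (xt - params["mu"]) ** 2 / np.exp(lv)
        if kind == "count":
            xt = self.codec.target(x)
            a = params["log_rate"]
            return xt * a - np.exp(a) - gammaln(xt + 1.0)
        codes = self.codec.target(x)
        return np.log(params["probs"][np.arange(len(codes)), codes] + 1e-10)

    def sample(self, params: dict, rng: np.random.Generator) -> np.ndarray:
        kind = self.codec.kind
        c = self.codec
        if kind in ("real", "positive_real"):
            draw = params["mu"] + np.exp(0.5 * params["logvar"]) * rng.standard_normal(
                len(params["mu"])
            )
            y = draw * c.s + c.m
            return np.exp(y) if kind == "positive_real" else y
        if kind == "count":
            return rng.poisson(np.exp(np.clip(params["log_rate"], None, 20.0))).astype(float)
        p = params["probs"]
        u = rng.random((len(p), 1))
        return (u > np.cumsum(p, axis=1)[:, :-1]).sum(axis=1).astype(float)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class Hivae:
    """One trained autoencoder over a module slice of shape (N, V, D)."""

    def __init__(self, specs: Sequence[VariableSpec], n_visits: int, config: HivaeConfig):
        if config.variant == "baseline" and n_visits != 1:
            raise ValueError("baseline variant encodes a single visit per model")
        self.specs = list(specs)
        self.V = n_visits
        self.config = config
        self.codecs: list[_Codec] | None = None
        self._params: list[Tensor] = []
        self.loss_history: list[float] = []

    # -- construction -------------------------------------------------------
    def _build(self, values: np.ndarray, mask: np.ndarray) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.codecs = []
        for d, spec in enumerate(self.specs):
            obs = values[:, :, d][mask[:, :, d]]
            self.codecs.append(_Codec(spec, obs))
        self.F = sum(c.n_enc for c in self.codecs)

        if cfg.variant == "MT":
            self.lstm = LSTM(self.F, cfg.lstm_units, rng)
            r_dim = cfg.lstm_units
            enc_layers = self.lstm.params
        else:
            self.enc_in = Dense(self.F * self.V, cfg.hidden_dim, rng)
            r_dim = cfg.hidden_dim
            enc_layers = self.enc_in.params

        self.enc_s = Dense(r_dim, cfg.s_dim, rng)
        self.enc_zh = Dense(r_dim + cfg.s_dim, cfg.hidden_dim, rng)
        self.enc_mu = Dense(cfg.hidden_dim, cfg.z_dim, rng)
        self.enc_lv = Dense(cfg.hidden_dim, cfg.z_dim, rng)
        self.prior_mu = Tensor(rng.normal(0.0, 0.5, (cfg.s_dim, cfg.z_dim)))
        self.dec_h = Dense(cfg.z_dim, cfg.hidden_dim, rng)
        self.dec_y = Dense(cfg.hidden_dim, self.V * cfg.y_dim, rng)

        self.heads = [
            [_Head(self.codecs[d], cfg.y_dim + cfg.s_dim, rng) for d in range(len(self.specs))]
            for _ in range(self.V)
        ]
        self._params = (
            enc_layers
            + self.enc_s.params + self.enc_zh.params
            + self.enc_mu.params + self.enc_lv.params
            + [self.prior_mu]
            + self.dec_h.params + self.dec_y.params
            + [p for row in self.heads for h in row for p in h.params]
        )

    # -- encoder forward ----------------------------------------------------
    def _visit_features(self, values: np.ndarray, mask: np.ndarray) -> list[np.ndarray]:
        steps = []
        for v in range(self.V):
            cols = [
                c.enc_features(values[:, v, d], mask[:, v, d])
                for d, c in enumerate(self.codecs)
            ]
            steps.append(np.concatenate(cols, axis=1))
        return steps

    def _representation(self, steps: list[np.ndarray]) -> Tensor:
        if self.config.variant == "MT":
            return self.lstm([constant(s) for s in steps])
        flat = constant(np.concatenate(steps, axis=1))
        return self.enc_in(flat).tanh()

    def _posterior_z(self, r: Tensor, e_k: np.ndarray) -> tuple[Tensor, Tensor]:
        h = self.enc_zh(concat([r, constant(e_k)], axis=1)).tanh()
        mu = self.enc_mu(h)
        logvar = self.enc_lv(h).tanh() * 4.0  # keep variances in a sane band
        return mu, logvar

    def _decode_Y(self, z: Tensor) -> Tensor:
        return self.dec_y(self.dec_h(z).tanh())

    def _recon_terms(self, z: Tensor, e_k: np.ndarray, values, mask, weights: Tensor) -> Tensor:
        """Sum over observed cells of q_s-weighted log-likelihoods (scalar)."""
        Y = self._decode_Y(z)
        e = constant(e_k)
        y_dim = self.config.y_dim
        total = None
        for v in range(self.V):
            Yv = Y[:, v * y_dim : (v + 1) * y_dim]
            inp = concat([Yv, e], axis=1)
            for d, head in enumerate(self.heads[v]):
                ll = head.loglik(inp, values[:, v, d], mask[:, v, d])
                term = (weights * ll).sum()
                total = term if total is None else total + term
        return total

    # -- training loss ------------------------------------------------------
    def _loss(self, values, mask, rng: np.random.Generator) -> Tensor:
        cfg = self.config
        n = values.shape[0]
        steps = self._visit_features(values, mask)
        r = self._representation(steps)
        log_qs = self.enc_s(r).log_softmax(axis=1)
        qs = log_qs.exp()
        kl_s = (qs * (log_qs - float(np.log(1.0 / cfg.s_dim)))).sum()

        total = None
        for k in range(cfg.s_dim):
            e_k = np.tile(np.eye(cfg.s_dim)[k], (n, 1))
            mu, logvar = self._posterior_z(r, e_k)
            eps = constant(rng.standard_normal((n, cfg.z_dim)))
            z = mu + (logvar * 0.5).exp() * eps
            w = qs[:, k]
            recon = self._recon_terms(z, e_k, values, mask, w)
            prior_k = self.prior_mu[k : k + 1, :]
            kl_z = (
                (logvar.exp() + (mu - prior_k) ** 2.0 - 1.0 - logvar).sum(axis=1) * 0.5
            )
            contrib = recon - (w * kl_z).sum()
            total = contrib if total is None else total + contrib
        elbo = total - kl_s
        return elbo * (-1.0 / n)

    def fit(self, values: np.ndarray, mask: np.ndarray) -> "Hivae":
        if np.isnan(values[mask]).any():
            raise ValueError("NaN in an observed cell")
        cfg = self.config
        self._build(values, mask)
        opt = Adam(self._params, lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)
        n = values.shape[0]
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                loss = self._loss(values[idx], mask[idx], rng)
                if not np.isfinite(loss.data):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch} "
                        f"(variant={cfg.variant}, D={len(self.specs)}, V={self.V})"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            self.loss_history.append(epoch_loss / n)
        return self

    # -- posterior extraction ------------------------------------------------
    def _check_schema(self, values: np.ndarray) -> None:
        if values.shape[2] != len(self.specs):
            raise SchemaError(
                f"batch has {values.shape[2]} variables, module declares {len(self.specs)}"
            )

    def encode(self, values: np.ndarray, mask: np.ndarray) -> ModuleEncoding:
        """Deterministic posterior modes: argmax component, mean code."""
        self._check_schema(values)
        n = values.shape[0]
        cfg = self.config
        steps = self._visit_features(values, mask)
        r = self._representation(steps)
        qs = self.enc_s(r).log_softmax(axis=1).exp().data
        s_idx = qs.argmax(axis=1)
        z = np.empty((n, cfg.z_dim))
        for k in range(cfg.s_dim):
            sel = s_idx == k
            if not sel.any():
                continue
            e_k = np.tile(np.eye(cfg.s_dim)[k], (n, 1))
            mu, _ = self._posterior_z(r, e_k)
            z[sel] = mu.data[sel]
        return ModuleEncoding(s=s_idx, z=z, q_s=qs)

    # -- decoder-side API ----------------------------------------------------
    def decoder_params(self, encoding: ModuleEncoding) -> list[list[dict]]:
        """Per-(visit, variable) distribution parameters for each row."""
        e = encoding.s_onehot
        h = np.tanh(encoding.z @ self.dec_h.W.data + self.dec_h.b.data)
        Y = h @ self.dec_y.W.data + self.dec_y.b.data
        y_dim = self.config.y_dim
        params = []
        for v in range(self.V):
            inp = np.concatenate([Y[:, v * y_dim : (v + 1) * y_dim], e], axis=1)
            params.append([head.np_params(inp) for head in self.heads[v]])
        return params

    def sample_cells(self, encoding: ModuleEncoding, rng: np.random.Generator) -> np.ndarray:
        """Draw an (N, V, D) block from the per-cell likelihood heads."""
        params = self.decoder_params(encoding)
        n = len(encoding.s)
        out = np.empty((n, self.V, len(self.specs)))
        for v in range(self.V):
            for d, head in enumerate(self.heads[v]):
                out[:, v, d] = head.sample(params[v][d], rng)
        return out

    # -- masked ELBO on fixed posterior/decoder parameters --------------------
    def posterior(self, values: np.ndarray, mask: np.ndarray) -> dict:
        """Full posterior: q(s|x) and per-component q(z|x,s) means/variances."""
        self._check_schema(values)
        n = values.shape[0]
        cfg = self.config
        steps = self._visit_features(values, mask)
        r = self._representation(steps)
        qs = self.enc_s(r).log_softmax(axis=1).exp().data
        mus = np.empty((cfg.s_dim, n, cfg.z_dim))
        lvs = np.empty((cfg.s_dim, n, cfg.z_dim))
        for k in range(cfg.s_dim):
            e_k = np.tile(np.eye(cfg.s_dim)[k], (n, 1))
            mu, lv = self._posterior_z(r, e_k)
            mus[k], lvs[k] = mu.data, lv.data
        return {"q_s": qs, "mu": mus, "logvar": lvs}

    def component_decoder_params(self, posterior: dict) -> list[list[list[dict]]]:
        """Decoder parameters at the posterior-mean code of every component."""
        out = []
        for k in range(self.config.s_dim):
            n = posterior["q_s"].shape[0]
            enc = ModuleEncoding(
                s=np.full(n, k), z=posterior["mu"][k], q_s=np.eye(self.config.s_dim)[
                    np.full(n, k)
                ],
            )
            out.append(self.decoder_params(enc))
        return out

    def cell_loglik(self, values: np.ndarray, decoder_params) -> np.ndarray:
        """(s_dim, N, V, D) log-likelihood of every cell under each component."""
        K = self.config.s_dim
        n = values.shape[0]
        out = np.empty((K, n, self.V, len(self.specs)))
        for k in range(K):
            for v in range(self.V):
                for d, head in enumerate(self.heads[v]):
                    out[k, :, v, d] = head.np_loglik(decoder_params[k][v][d], values[:, v, d])
        return out

    def elbo(self, values, mask, posterior=None, decoder_params=None) -> float:
        """Masked ELBO: observed-cell reconstruction minus the two KL terms.

        With `posterior` and `decoder_params` held fixed, removing a cell from
        the mask changes the value by exactly that cell's (q_s-weighted)
        log-likelihood, and the stored value of a masked cell is irrelevant.
        """
        if np.isnan(values[mask]).any():
            raise ValueError("NaN in an observed cell")
        if posterior is None:
            posterior = self.posterior(values, mask)
        if decoder_params is None:
            decoder_params = self.component_decoder_params(posterior)
        qs = posterior["q_s"]  # (N, K)
        ll = self.cell_loglik(values, decoder_params)  # (K, N, V, D)
        masked = np.where(mask[None, :, :, :], ll, 0.0)
        recon = np.einsum("nk,knvd->", qs, masked)

        K = self.config.s_dim
        kl_s = float(np.sum(qs * (np.log(qs + 1e-12) - np.log(1.0 / K))))
        kl_z = 0.0
        for k in range(K):
            mu, lv = posterior["mu"][k], posterior["logvar"][k]
            per_n = 0.5 * np.sum(
                np.exp(lv) + (mu - self.prior_mu.data[k]) ** 2 - 1.0 - lv, axis=1
            )
            kl_z += float(np.sum(qs[:, k] * per_n))
        return recon - kl_s - kl_z


def fit_module(
    values: np.ndarray,
    mask: np.ndarray,
    specs: Sequence[VariableSpec],
    config: HivaeConfig,
) -> tuple[Hivae, ModuleEncoding]:
    """Train one module and return it with deterministic encodings."""
    if values.shape[0] < 2 or not mask.any():
        raise ValueError("need at least 2 participants with some observed data")
    model = Hivae(specs, n_visits=values.shape[1], config=config)
    model.fit(values, mask)
    return model, model.encode(values, mask)
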