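"""Bayesian network: constrained search, ML parameters, ancestral sampling."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from vambn import (
    BayesNet,
    EdgeConstraints,
    assemble_bn_inputs,
    fit_parameters,
    learn_structure,
    sample_embeddings,
)
from vambn.hivae import ModuleEncoding
from vambn.mbn import ConstraintError, _Scorer


def _chain_data(n=2000, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    y = 2.0 * x + rng.normal(0, 0.5, n)
    z = -1.5 * y + rng.normal(0, 0.5, n)
    return pd.DataFrame({"X": x, "Y": y, "Z": z})


def _all_dags(nodes):
    pairs = list(itertools.combinations(nodes, 2))
    for states in itertools.product([0, 1, 2], repeat=len(pairs)):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for (a, b), s in zip(pairs, states):
            if s == 1:
                g.add_edge(a, b)
            elif s == 2:
                g.add_edge(b, a)
        if nx.is_directed_acyclic_graph(g):
            yield g


def test_chain_recovery_matches_exhaustive_scoring():
    data = _chain_data()
    net = learn_structure(data, seed=0)
    scorer = _Scorer(data, {})
    dags = list(_all_dags(["X", "Y", "Z"]))
    assert len(dags) == 25
    best = max(dags, key=scorer.total)
    # hill climbing attains the global optimum of the exhaustive scan
    assert np.isclose(scorer.total(net.graph()), scorer.total(best))
    # the learned structure lies in the chain's equivalence class:
    # skeleton X-Y-Z without the X-Z edge and no collider at Y
    skel = {frozenset(e) for e in net.edges}
    assert skel == {frozenset({"X", "Y"}), frozenset({"Y", "Z"})}
    assert not ({("X", "Y"), ("Z", "Y")} <= net.edges)


@pytest.mark.parametrize("seed", range(5))
def test_constraint_soundness_on_randomized_lists(seed):
    rng = np.random.default_rng(seed)
    nodes = ["A", "B", "C", "D"]
    data = pd.DataFrame(rng.normal(size=(300, 4)), columns=nodes)
    data["B"] += 1.5 * data["A"]
    data["D"] += -2.0 * data["C"]
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    rng.shuffle(pairs)
    white = frozenset(pairs[:1])
    black = frozenset(p for p in pairs[1:4] if p[::-1] not in white)
    constraints = EdgeConstraints(blacklist=black, whitelist=white)
    net = learn_structure(data, constraints, seed=seed)
    assert white <= net.edges
    assert not (black & net.edges)
    assert nx.is_directed_acyclic_graph(net.graph())


def test_whitelist_cycle_rejected():
    data = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 2)), columns=["A", "B"])
    with pytest.raises(ConstraintError):
        learn_structure(
            data, EdgeConstraints(whitelist={("A", "B"), ("B", "A")}), seed=0
        )


def test_overlapping_lists_rejected():
    with pytest.raises(ConstraintError):
        EdgeConstraints(blacklist={("A", "B")}, whitelist={("A", "B")})


def test_root_gaussian_ml_moments():
    rng = np.random.default_rng(1)
    y = rng.normal(3.0, 2.0, 4000)
    data = pd.DataFrame({"Y": y})
    net = fit_parameters(BayesNet(nodes=["Y"], discrete={}), data)
    reg = net.parameters["Y"]["regressions"][()]
    assert np.isclose(reg["intercept"], y.mean())
    assert np.isclose(reg["variance"], y.var())


def test_linear_gaussian_weight_recovered_within_3se():
    rng = np.random.default_rng(2)
    n = 5000
    z1 = rng.normal(0, 1, n)
    z2 = 2.0 * z1 + rng.normal(0, 0.1, n)
    data = pd.DataFrame({"z1": z1, "z2": z2})
    net = fit_parameters(
        BayesNet(nodes=["z1", "z2"], discrete={}, edges={("z1", "z2")}), data
    )
    reg = net.parameters["z2"]["regressions"][()]
    # closed-form OLS oracle and its standard error
    beta_hat = np.dot(z1 - z1.mean(), z2 - z2.mean()) / np.sum((z1 - z1.mean()) ** 2)
    se = 0.1 / np.sqrt(np.sum((z1 - z1.mean()) ** 2))
    assert np.isclose(reg["coefs"][0], beta_hat, atol=1e-10)
    assert abs(reg["coefs"][0] - 2.0) < 3 * se


def test_categorical_root_frequencies():
    rng = np.random.default_rng(3)
    c = rng.choice([0, 1], p=[0.7, 0.3], size=5000)
    data = pd.DataFrame({"c": c})
    net = fit_parameters(BayesNet(nodes=["c"], discrete={"c": [0, 1]}), data)
    cpt = net.parameters["c"]["cpt"][()]
    assert np.allclose(cpt, [(c == 0).mean(), (c == 1).mean()])
    assert abs(cpt[0] - 0.7) < 0.02


def test_sampling_moments_and_determinism():
    net = fit_parameters(
        BayesNet(nodes=["z1", "z2"], discrete={}, edges={("z1", "z2")}),
        _chain_data(5000, seed=4)[["X", "Y"]].rename(columns={"X": "z1", "Y": "z2"}),
    )
    n = 20000
    samp = sample_embeddings(net, n, seed=7)
    again = sample_embeddings(net, n, seed=7)
    pd.testing.assert_frame_equal(samp, again)
    # analytic moments of the fitted linear-Gaussian model
    r1 = net.parameters["z1"]["regressions"][()]
    r2 = net.parameters["z2"]["regressions"][()]
    w = r2["coefs"][0]
    mean2 = r2["intercept"] + w * r1["intercept"]
    var2 = w**2 * r1["variance"] + r2["variance"]
    se_mean = np.sqrt(var2 / n)
    se_var = var2 * np.sqrt(2.0 / n)
    assert abs(samp["z2"].mean() - mean2) < 4 * se_mean
    assert abs(samp["z2"].var() - var2) < 4 * se_var


def test_empty_sample_and_negative_n():
    net = fit_parameters(BayesNet(nodes=["z"], discrete={}), pd.DataFrame({"z": [0.0, 1.0]}))
    assert len(sample_embeddings(net, 0, seed=0)) == 0
    with pytest.raises(ValueError):
        sample_embeddings(net, -1, seed=0)


def test_refit_on_own_sample_recovers_parameters():
    rng = np.random.default_rng(5)
    base = pd.DataFrame({
        "s": rng.choice([0, 1], p=[0.4, 0.6], size=3000),
        "z": rng.normal(0, 1, 3000),
    })
    base["z"] += np.where(base["s"] == 1, 2.0, -1.0)
    structure = BayesNet(nodes=["s", "z"], discrete={"s": [0, 1]}, edges={("s", "z")})
    net = fit_parameters(structure, base)
    samp = sample_embeddings(net, 30000, seed=8)
    refit = fit_parameters(structure, samp)
    for combo in [(0,), (1,)]:
        a = net.parameters["z"]["regressions"][combo]
        b = refit.parameters["z"]["regressions"][combo]
        assert abs(a["intercept"] - b["intercept"]) < 0.05
        assert abs(a["variance"] - b["variance"]) < 0.05
    assert np.allclose(net.parameters["s"]["cpt"][()],
                       refit.parameters["s"]["cpt"][()], atol=0.02)


def test_assemble_node_counts():
    rng = np.random.default_rng(0)
    idx = pd.Index([f"P{i}" for i in range(10)], name="pers_id")
    encodings = {
        m: ModuleEncoding(
            s=rng.integers(0, 3, 10), z=rng.normal(size=(10, 2)),
            q_s=np.full((10, 3), 1 / 3),
        )
        for m in ("T", "N", "A", "S")
    }
    indicators = pd.DataFrame(
        rng.random((10, 16)) > 0.2, index=idx,
        columns=[f"visit{v:02d}" for v in range(16)],
    )
    cov = pd.DataFrame({"sex": rng.integers(0, 2, 10), "height0": rng.normal(size=10)},
                       index=idx)
    table, discrete = assemble_bn_inputs(encodings, idx, cov, ["sex"], indicators)
    # 4 s-nodes + 8 z-nodes + 16 indicators + 2 covariates
    assert table.shape[1] == 30
    assert sum(c.endswith("_s") for c in table.columns) == 4
    assert set(discrete) >= {"T_s", "visit00", "sex"}
    assert "height0" not in discrete


def test_assemble_index_mismatch():
    idx = pd.Index(["a", "b"], name="pers_id")
    enc = {"M": ModuleEncoding(s=np.zeros(3, int), z=np.zeros((3, 1)),
                               q_s=np.ones((3, 1)))}
    with pytest.raises(ValueError):
        assemble_bn_inputs(enc, idx)


def test_json_round_trip(tmp_path):
    data = _chain_data(500, seed=6)
    net = fit_parameters(learn_structure(data, seed=0), data)
    path = tmp_path / "net.json"
    net.to_json(path)
    back = BayesNet.from_json(path)
    assert back.edges == net.edges
    samp_a = sample_embeddings(net, 50, seed=1)
    samp_b = sample_embeddings(back, 50, seed=1)
    pd.testing.assert_frame_equal(samp_a, samp_b)
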