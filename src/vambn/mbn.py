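"""Conditional linear-Gaussian Bayesian network over module embeddings.

Nodes are either discrete (module components s, visit-attendance indicators,
categorical covariates) or Gaussian (module codes z, continuous covariates).
The conditional-Gaussian restriction applies: discrete nodes never have
Gaussian parents.  Structure is learned by score-based hill climbing (BIC)
under user-supplied black/white edge lists; parameters are maximum-likelihood
conditional probability tables and per-discrete-configuration linear
regressions; synthesis is ancestral sampling in topological order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeConstraints",
    "BayesNet",
    "assemble_bn_inputs",
    "learn_structure",
    "fit_parameters",
    "sample_embeddings",
]

Edge = tuple[str, str]


class ConstraintError(ValueError):
    pass


@dataclass(frozen=True)
class EdgeConstraints:
    """Forbidden and mandatory directed edges for structure search."""

    blacklist: frozenset = frozenset()
    whitelist: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "blacklist", frozenset(map(tuple, self.blacklist)))
        object.__setattr__(self, "whitelist", frozenset(map(tuple, self.whitelist)))
        overlap = self.blacklist & self.whitelist
        if overlap:
            raise ConstraintError(f"edges both black- and whitelisted: {sorted(overlap)}")

    @classmethod
    def from_csv(cls, blacklist_path=None, whitelist_path=None) -> "EdgeConstraints":
        def read(path):
            if path is None:
                return frozenset()
            df = pd.read_csv(path)
            return frozenset(zip(df.iloc[:, 0], df.iloc[:, 1]))

        return cls(blacklist=read(blacklist_path), whitelist=read(whitelist_path))


@dataclass
class BayesNet:
    """DAG plus ML parameters; `discrete` maps node -> ordered level list."""

    nodes: list[str]
    discrete: dict[str, list]
    edges: set = field(default_factory=set)
    parameters: dict = field(default_factory=dict)

    def graph(self) -> nx.DiGraph:
        # sorted insertion keeps iteration (and thus sampling) order stable
        # across processes regardless of set-hash randomisation
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    def parents(self, node: str) -> list[str]:
        return sorted(u for u, v in self.edges if v == node)

    # ---- serialisation ---------------------------------------------------
    def to_json(self, path=None) -> str:
        def clean(obj):
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(x) for x in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        params = {}
        for node, p in self.parameters.items():
            q = dict(p)
            if "cpt" in q:
                q["cpt"] = {json.dumps(clean(k)): clean(v) for k, v in q["cpt"].items()}
            if "regressions" in q:
                q["regressions"] = {
                    json.dumps(clean(k)): clean(v) for k, v in q["regressions"].items()
                }
            params[node] = clean(q)
        doc = json.dumps(
            {
                "nodes": self.nodes,
                "discrete": clean(self.discrete),
                "edges": sorted(map(list, self.edges)),
                "parameters": params,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_json(cls, source) -> "BayesNet":
        doc = json.loads(open(source).read() if not str(source).lstrip().startswith("{") else source)
        params = {}
        for node, p in doc["parameters"].items():
            q = dict(p)
            if "cpt" in q:
                q["cpt"] = {tuple(json.loads(k)): np.asarray(v) for k, v in q["cpt"].items()}
            if "regressions" in q:
                q["regressions"] = {tuple(json.loads(k)): v for k, v in q["regressions"].items()}
            params[node] = q
        return cls(
            nodes=doc["nodes"],
            discrete={k: list(v) for k, v in doc["discrete"].items()},
            edges={tuple(e) for e in doc["edges"]},
            parameters=params,
        )

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph(), path)


# ---------------------------------------------------------------------------
# node-value table assembly
# ---------------------------------------------------------------------------


def assemble_bn_inputs(
    encodings: Mapping[str, "ModuleEncoding"],
    index: pd.Index,
    covariates: pd.DataFrame | None = None,
    discrete_covariates: Iterable[str] = (),
    indicators: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, list]]:
    """One column per BN node: `<mod>_s`, `<mod>_z<k>`, indicators, covariates.

    Returns the table plus the discrete-node level map.  All inputs must share
    the participant index.
    """
    table = pd.DataFrame(index=index)
    discrete: dict[str, list] = {}
    for mod in sorted(encodings):
        enc = encodings[mod]
        if len(enc.s) != len(index):
            raise ValueError(f"module {mod!r}: participant-index mismatch")
        s_col = f"{mod}_s"
        table[s_col] = enc.s.astype(int)
        discrete[s_col] = list(range(enc.q_s.shape[1]))
        for k in range(enc.z.shape[1]):
            table[f"{mod}_z{k}"] = enc.z[:, k]
    if indicators is not None:
        if not indicators.index.equals(index):
            raise ValueError("indicator table: participant-index mismatch")
        for col in indicators.columns:
            table[col] = indicators[col].astype(int)
            discrete[col] = [0, 1]
    if covariates is not None:
        if not covariates.index.equals(index):
            raise ValueError("covariate table: participant-index mismatch")
        disc = set(discrete_covariates)
        for col in covariates.columns:
            table[col] = covariates[col]
            if col in disc:
                discrete[col] = sorted(pd.unique(covariates[col]).tolist())
    return table, discrete


# ---------------------------------------------------------------------------
# BIC scoring
# ---------------------------------------------------------------------------

_LOG2PI = float(np.log(2.0 * np.pi))
_VAR_FLOOR = 1e-9


def _configs(data: pd.DataFrame, disc_parents: list[str], discrete: dict):
    if not disc_parents:
        yield (), np.ones(len(data), dtype=bool)
        return
    import itertools

    levels = [discrete[p] for p in disc_parents]
    cols = [data[p].to_numpy() for p in disc_parents]
    for combo in itertools.product(*levels):
        sel = np.ones(len(data), dtype=bool)
        for c, val in zip(cols, combo):
            sel &= c == val
        yield combo, sel


def _gaussian_fit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS coefficients (incl. intercept) and MLE residual variance."""
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    var = max(float(np.mean(resid**2)), _VAR_FLOOR)
    return beta, var


def _local_score(node: str, parents: frozenset, data: pd.DataFrame, discrete: dict) -> float:
    """BIC = log-likelihood - 0.5 * log(N) * n_free_parameters."""
    n = len(data)
    disc_parents = sorted(p for p in parents if p in discrete)
    cont_parents = sorted(p for p in parents if p not in discrete)
    q = int(np.prod([len(discrete[p]) for p in disc_parents])) if disc_parents else 1

    if node in discrete:
        if cont_parents:
            return -np.inf  # conditional-Gaussian restriction
        r = len(discrete[node])
        ll = 0.0
        y = data[node].to_numpy()
        for _, sel in _configs(data, disc_parents, discrete):
            n_c = int(sel.sum())
            if n_c == 0:
                continue
            counts = np.array([(y[sel] == lvl).sum() for lvl in discrete[node]], dtype=float)
            nz = counts > 0
            ll += float(np.sum(counts[nz] * np.log(counts[nz] / n_c)))
        n_params = q * (r - 1)
        return ll - 0.5 * np.log(n) * n_params

    y = data[node].to_numpy(dtype=float)
    Xall = data[cont_parents].to_numpy(dtype=float) if cont_parents else np.empty((n, 0))
    ll = 0.0
    for _, sel in _configs(data, disc_parents, discrete):
        n_c = int(sel.sum())
        if n_c == 0:
            continue
        _, var = _gaussian_fit(y[sel], Xall[sel])
        ll += -0.5 * n_c * (_LOG2PI + np.log(var) + 1.0)
    n_params = q * (len(cont_parents) + 2)
    return ll - 0.5 * np.log(n) * n_params


class _Scorer:
    def __init__(self, data: pd.DataFrame, discrete: dict):
        self.data = data
        self.discrete = discrete
        self.cache: dict[tuple[str, frozenset], float] = {}

    def local(self, node: str, parents: frozenset) -> float:
        key = (node, parents)
        if key not in self.cache:
            self.cache[key] = _local_score(node, parents, self.data, self.discrete)
        return self.cache[key]

    def total(self, graph: nx.DiGraph) -> float:
        return sum(self.local(n, frozenset(graph.predecessors(n))) for n in graph.nodes)


# ---------------------------------------------------------------------------
# hill climbing
# ---------------------------------------------------------------------------


def _edge_allowed(u: str, v: str, discrete: dict, constraints: EdgeConstraints) -> bool:
    if (u, v) in constraints.blacklist:
        return False
    if v in discrete and u not in discrete:
        return False  # no Gaussian parents for discrete nodes
    return True


def learn_structure(
    data: pd.DataFrame,
    constraints: EdgeConstraints | None = None,
    seed: int = 0,
    discrete: Mapping[str, list] | None = None,
    max_parents: int = 4,
    n_restarts: int = 5,
    max_iter: int = 200,
) -> BayesNet:
    """Score-based DAG search honouring all constraints.

    Greedy best-improvement hill climbing over add/delete/reverse moves with
    seeded random restarts; ties are broken by lexicographic move order so the
    result is deterministic under a fixed seed.
    """
    constraints = constraints or EdgeConstraints()
    discrete = dict(discrete or {})
    nodes = sorted(data.columns)
    rng = np.random.default_rng(seed)
    scorer = _Scorer(data, discrete)

    base = nx.DiGraph()
    base.add_nodes_from(nodes)
    for u, v in sorted(constraints.whitelist):
        if u not in base or v not in base:
            raise ConstraintError(f"whitelist edge {u}->{v} references unknown node")
        if not _edge_allowed(u, v, discrete, constraints):
            raise ConstraintError(f"whitelist edge {u}->{v} violates typing/blacklist")
        base.add_edge(u, v)
    if not nx.is_directed_acyclic_graph(base):
        raise ConstraintError("whitelist forces a cycle")

    def climb(graph: nx.DiGraph) -> tuple[nx.DiGraph, float]:
        score = scorer.total(graph)
        for _ in range(max_iter):
            best_gain, best_move = 1e-9, None
            for u in nodes:
                for v in nodes:
                    if u == v:
                        continue
                    has = graph.has_edge(u, v)
                    pv = frozenset(graph.predecessors(v))
                    if not has:
                        if (
                            _edge_allowed(u, v, discrete, constraints)
                            and len(pv) < max_parents
                            and not nx.has_path(graph, v, u)
                        ):
                            gain = scorer.local(v, pv | {u}) - scorer.local(v, pv)
                            # ties resolved by the sorted (u, v) scan order
                            if gain > best_gain:
                                best_gain, best_move = gain, ("add", u, v)
                    else:
                        if (u, v) not in constraints.whitelist:
                            gain = scorer.local(v, pv - {u}) - scorer.local(v, pv)
                            move = ("delete", u, v)
                            if gain > best_gain:
                                best_gain, best_move = gain, move
                            # reverse = delete + add opposite
                            if _edge_allowed(v, u, discrete, constraints):
                                pu = frozenset(graph.predecessors(u))
                                graph.remove_edge(u, v)
                                creates_cycle = nx.has_path(graph, u, v)
                                graph.add_edge(u, v)
                                if not creates_cycle and len(pu) < max_parents:
                                    gain = (
                                        scorer.local(v, pv - {u})
                                        - scorer.local(v, pv)
                                        + scorer.local(u, pu | {v})
                                        - scorer.local(u, pu)
                                    )
                                    move = ("reverse", u, v)
                                    if gain > best_gain:
                                        best_gain, best_move = gain, move
            if best_move is None:
                break
            kind, u, v = best_move
            if kind == "add":
                graph.add_edge(u, v)
            elif kind == "delete":
                graph.remove_edge(u, v)
            else:
                graph.remove_edge(u, v)
                graph.add_edge(v, u)
            score += best_gain
        return graph, scorer.total(graph)

    best_graph, best_score = climb(base.copy())
    candidates = [
        (u, v)
        for u in nodes
        for v in nodes
        if u != v and _edge_allowed(u, v, discrete, constraints)
    ]
    for _ in range(max(n_restarts - 1, 0)):
        g = base.copy()
        rng.shuffle(candidates)
        for u, v in candidates[: len(nodes)]:
            if (
                not g.has_edge(u, v)
                and g.in_degree(v) < max_parents
                and not nx.has_path(g, v, u)
            ):
                g.add_edge(u, v)
        g, s = climb(g)
        if s > best_score + 1e-9:
            best_graph, best_score = g, s

    net = BayesNet(nodes=nodes, discrete={k: list(v) for k, v in discrete.items()},
                   edges=set(best_graph.edges))
    for u, v in constraints.whitelist:
        assert (u, v) in net.edges
    return net


# ---------------------------------------------------------------------------
# parameter fitting and sampling
# ---------------------------------------------------------------------------


def fit_parameters(structure: BayesNet, data: pd.DataFrame) -> BayesNet:
    """Maximum-likelihood CPTs and per-configuration linear regressions."""
    discrete = structure.discrete
    params: dict[str, dict] = {}
    for node in structure.nodes:
        parents = structure.parents(node)
        disc_parents = sorted(p for p in parents if p in discrete)
        cont_parents = sorted(p for p in parents if p not in discrete)
        if node in discrete:
            levels = discrete[node]
            y = data[node].to_numpy()
            marg_counts = np.array([(y == lvl).sum() for lvl in levels], dtype=float)
            marginal = (marg_counts + 1e-9) / (marg_counts + 1e-9).sum()
            cpt = {}
            for combo, sel in _configs(data, disc_parents, discrete):
                n_c = int(sel.sum())
                if n_c == 0:
                    logger.warning(
                        "node %s: empty parent configuration %s, using marginal", node, combo
                    )
                    cpt[combo] = marginal.copy()
                    continue
                counts = np.array([(y[sel] == lvl).sum() for lvl in levels], dtype=float)
                cpt[combo] = counts / n_c
            params[node] = {
                "type": "discrete",
                "levels": levels,
                "disc_parents": disc_parents,
                "cpt": cpt,
                "marginal": marginal,
            }
        else:
            y = data[node].to_numpy(dtype=float)
            X = data[cont_parents].to_numpy(dtype=float) if cont_parents else np.empty((len(y), 0))
            marg_beta, marg_var = _gaussian_fit(y, np.empty((len(y), 0)))
            regs = {}
            for combo, sel in _configs(data, disc_parents, discrete):
                n_c = int(sel.sum())
                if n_c <= len(cont_parents) + 1:
                    if n_c == 0:
                        logger.warning(
                            "node %s: empty parent configuration %s, using marginal fit",
                            node, combo,
                        )
                    beta = np.concatenate([marg_beta, np.zeros(len(cont_parents))])
                    var = marg_var
                else:
                    beta, var = _gaussian_fit(y[sel], X[sel])
                regs[combo] = {
                    "intercept": float(beta[0]),
                    "coefs": [float(b) for b in beta[1:]],
                    "variance": float(var),
                }
            params[node] = {
                "type": "gaussian",
                "disc_parents": disc_parents,
                "cont_parents": cont_parents,
                "regressions": regs,
                "marginal": {"intercept": float(marg_beta[0]), "variance": float(marg_var)},
            }
    return BayesNet(
        nodes=structure.nodes,
        discrete=dict(discrete),
        edges=set(structure.edges),
        parameters=params,
    )


def sample_embeddings(net: BayesNet, n: int, seed: int = 0) -> pd.DataFrame:
    """Ancestral sampling of `n` synthetic participants' node values."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if not net.parameters:
        raise ValueError("network is not parameterised; call fit_parameters first")
    rng = np.random.default_rng(seed)
    order = list(nx.lexicographical_topological_sort(net.graph()))
    out = pd.DataFrame(index=range(n))
    for node in order:
        p = net.parameters[node]
        if p["type"] == "discrete":
            levels = p["levels"]
            vals = np.empty(n, dtype=object)
            if not p["disc_parents"]:
                probs = p["cpt"][()]
                idx = rng.choice(len(levels), size=n, p=probs / probs.sum())
                vals[:] = [levels[i] for i in idx]
            else:
                configs = list(zip(*(out[q] for q in p["disc_parents"]))) if n else []
                for i in range(n):
                    probs = p["cpt"].get(tuple(configs[i]), p["marginal"])
                    j = rng.choice(len(levels), p=probs / probs.sum())
                    vals[i] = levels[j]
            out[node] = vals
            try:
                out[node] = out[node].astype(type(levels[0]))
            except (TypeError, ValueError):
                pass
        else:
            cont = p["cont_parents"]
            Xc = out[cont].to_numpy(dtype=float) if cont else np.empty((n, 0))
            mean = np.empty(n)
            var = np.empty(n)
            if not p["disc_parents"]:
                reg = p["regressions"][()]
                mean[:] = reg["intercept"] + (
                    Xc @ np.asarray(reg["coefs"]) if cont else 0.0
                )
                var[:] = reg["variance"]
            else:
                configs = list(zip(*(out[q] for q in p["disc_parents"]))) if n else []
                for i in range(n):
                    reg = p["regressions"].get(tuple(configs[i]))
                    if reg is None:
                        mean[i] = p["marginal"]["intercept"]
                        var[i] = p["marginal"]["variance"]
                    else:
                        mean[i] = reg["intercept"] + (
                            Xc[i] @ np.asarray(reg["coefs"]) if cont else 0.0
                        )
                        var[i] = reg["variance"]
            out[node] = mean + np.sqrt(var) * rng.standard_normal(n)
    return out[net.nodes]
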