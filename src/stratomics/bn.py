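"""Gaussian Bayesian-network structure learning and driver scoring.

Structures are scored with the decomposable Gaussian BIC: each node
contributes the log-likelihood of its linear-Gaussian regression on its
parents minus ``(k/2) log n`` with ``k = |parents| + 2`` (coefficient block
plus intercept and variance); higher is better.  Greedy hill climbing over
add/delete/reverse moves finds local optima; a consensus DAG aggregates many
random restarts, drops direction-conflicted edges and is refined by
score-improving random single-edge perturbations.

A node's driver score is the total BIC drop over the rest of the network
when the node and its incident edges are removed (its own term is excluded
from both sides so totals are comparable); an empirical null re-scores
random non-candidate node sets.

Data are z-scored before fitting so node scores are on a comparable scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class DAGModel:
    nodes: list[str]
    parents: dict[str, frozenset[str]]
    node_scores: dict[str, float] = field(default_factory=dict)
    score: float = float("nan")

    def edges(self) -> list[tuple[str, str]]:
        return sorted((p, c) for c, ps in self.parents.items() for p in ps)

    def children(self, node: str) -> list[str]:
        return [c for c, ps in self.parents.items() if node in ps]

    def copy(self) -> "DAGModel":
        return DAGModel(list(self.nodes), dict(self.parents),
                        dict(self.node_scores), self.score)


def _is_acyclic(parents: dict[str, frozenset[str]]) -> bool:
    state: dict[str, int] = {}

    def visit(u: str) -> bool:
        state[u] = 1
        for v in parents[u]:
            s = state.get(v, 0)
            if s == 1 or (s == 0 and not visit(v)):
                return False
        state[u] = 2
        return True

    return all(visit(u) for u in parents if state.get(u, 0) == 0)


def _has_path(parents: dict[str, frozenset[str]], src: str, dst: str) -> bool:
    """True if dst is an ancestor-of/reachable-from src following parent links
    (i.e. there is a directed path dst -> ... -> src)."""
    stack = [src]
    seen = {src}
    while stack:
        u = stack.pop()
        for v in parents[u]:
            if v == dst:
                return True
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


class BicScorer:
    """Cached decomposable Gaussian BIC over a fixed z-scored data matrix."""

    def __init__(self, data: pd.DataFrame):
        X = data.to_numpy(dtype=float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.X = (X - mu) / sd
        self.nodes = list(data.columns)
        self.index = {c: i for i, c in enumerate(self.nodes)}
        self.n = X.shape[0]
        self.gram = self.X.T @ self.X
        self._cache: dict[tuple[str, frozenset[str]], float] = {}

    def node_score(self, node: str, parents: frozenset[str]) -> float:
        key = (node, parents)
        if key in self._cache:
            return self._cache[key]
        n = self.n
        j = self.index[node]
        syy = self.gram[j, j]
        if parents:
            pi = [self.index[p] for p in parents]
            sxx = self.gram[np.ix_(pi, pi)]
            sxy = self.gram[pi, j]
            try:
                beta = np.linalg.solve(sxx, sxy)
            except np.linalg.LinAlgError:
                self._cache[key] = -np.inf
                return -np.inf
            rss = syy - sxy @ beta
        else:
            rss = syy
        # data are centred so the intercept vanishes but still counts a parameter
        sigma2 = max(rss / n, 1e-300)
        loglik = -0.5 * n * (LOG2PI + np.log(sigma2) + 1.0)
        k = len(parents) + 2
        score = loglik - 0.5 * k * np.log(n)
        self._cache[key] = float(score)
        return float(score)

    def total(self, parents: dict[str, frozenset[str]]) -> float:
        return sum(self.node_score(v, ps) for v, ps in parents.items())

    def fit(self, parents: dict[str, frozenset[str]]) -> DAGModel:
        scores = {v: self.node_score(v, ps) for v, ps in parents.items()}
        return DAGModel(list(self.nodes), dict(parents), scores, sum(scores.values()))


def gaussian_bic(dag: DAGModel, data: pd.DataFrame) -> float:
    """Total decomposable Gaussian BIC of a DAG on the given data."""
    missing = [v for v in dag.nodes if v not in data.columns]
    if missing:
        raise ValueError(f"data missing nodes: {missing[:5]}")
    return BicScorer(data[dag.nodes]).total(dag.parents)


def random_dag(nodes: list[str], rng: np.random.Generator,
               edge_prob: float = 0.15, max_parents: int = 5) -> dict[str, frozenset[str]]:
    order = list(rng.permutation(nodes))
    parents = {v: set() for v in nodes}
    for i, child in enumerate(order):
        pool = order[:i]
        for p in pool:
            if len(parents[child]) >= max_parents:
                break
            if rng.random() < edge_prob:
                parents[child].add(p)
    return {v: frozenset(ps) for v, ps in parents.items()}


def _ancestor_sets(parents: dict[str, frozenset[str]]) -> dict[str, set[str]]:
    """Transitive ancestors of every node (memoized DFS over parent links)."""
    anc: dict[str, set[str]] = {}

    def visit(u: str) -> set[str]:
        if u in anc:
            return anc[u]
        anc[u] = set()  # placeholder guards against revisiting within a DAG
        out: set[str] = set()
        for p in parents[u]:
            out.add(p)
            out |= visit(p)
        anc[u] = out
        return out

    for v in parents:
        visit(v)
    return anc


def hill_climb(data: pd.DataFrame, start: dict[str, frozenset[str]] | None = None,
               max_parents: int = 5, seed: int = 0,
               scorer: BicScorer | None = None) -> DAGModel:
    """Greedy best-improvement search over add / delete / reverse moves."""
    sc = scorer or BicScorer(data)
    nodes = sc.nodes
    parents = {v: frozenset() for v in nodes} if start is None else dict(start)
    if not _is_acyclic(parents):
        raise ValueError("start graph is cyclic")
    node_scores = {v: sc.node_score(v, parents[v]) for v in nodes}
    while True:
        best_delta = 1e-10
        best_apply = None
        # one move is applied per sweep, so the closure stays valid throughout
        anc = _ancestor_sets(parents)
        for u in nodes:
            for v in nodes:
                if u == v:
                    continue
                if u in parents[v]:
                    # delete u -> v
                    new_ps = parents[v] - {u}
                    delta = sc.node_score(v, new_ps) - node_scores[v]
                    if delta > best_delta:
                        best_delta, best_apply = delta, [(v, new_ps)]
                    # reverse u -> v  =>  v -> u
                    if len(parents[u]) < max_parents:
                        tmp = dict(parents)
                        tmp[v] = parents[v] - {u}
                        if not _has_path(tmp, v, u):
                            new_u = parents[u] | {v}
                            delta = (sc.node_score(v, tmp[v]) - node_scores[v]
                                     + sc.node_score(u, new_u) - node_scores[u])
                            if delta > best_delta:
                                best_delta = delta
                                best_apply = [(v, tmp[v]), (u, new_u)]
                else:
                    # add u -> v
                    if len(parents[v]) >= max_parents:
                        continue
                    if v in anc[u]:  # v is an ancestor of u: edge would cycle
                        continue
                    new_ps = parents[v] | {u}
                    delta = sc.node_score(v, new_ps) - node_scores[v]
                    if delta > best_delta:
                        best_delta, best_apply = delta, [(v, new_ps)]
        if best_apply is None:
            break
        for v, ps in best_apply:
            parents[v] = ps
            node_scores[v] = sc.node_score(v, ps)
    return DAGModel(nodes, parents, node_scores, sum(node_scores.values()))


def _break_cycles(parents: dict[str, frozenset[str]],
                  support: dict[tuple[str, str], int]) -> dict[str, frozenset[str]]:
    parents = {v: set(ps) for v, ps in parents.items()}
    frozen = {v: frozenset(ps) for v, ps in parents.items()}
    while not _is_acyclic(frozen):
        # find one cycle via DFS and drop its lowest-support edge
        state: dict[str, int] = {}
        stack_path: list[str] = []
        cycle_edges: list[tuple[str, str]] = []

        def visit(u: str) -> bool:
            state[u] = 1
            stack_path.append(u)
            for v in frozen[u]:
                if state.get(v, 0) == 1:
                    i = stack_path.index(v)
                    chain = stack_path[i:] + [v]
                    cycle_edges.extend((chain[k + 1], chain[k])
                                       for k in range(len(chain) - 1))
                    return False
                if state.get(v, 0) == 0 and not visit(v):
                    return False
            stack_path.pop()
            state[u] = 2
            return True

        for u in frozen:
            if state.get(u, 0) == 0 and not visit(u):
                break
        drop = min(cycle_edges, key=lambda e: support.get(e, 0))
        parents[drop[1]].discard(drop[0])
        frozen = {v: frozenset(ps) for v, ps in parents.items()}
    return frozen


def consensus_dag(data: pd.DataFrame, n_starts: int = 150, refine_iters: int = 1000,
                  max_parents: int = 5, seed: int = 0) -> DAGModel:
    """Majority-vote consensus over hill climbs from random starts.

    An edge u->v is retained iff it appears as u->v in more than half of the
    results and its reverse is not also majority-supported (direction
    conflicts are removed).  The assembled graph is then refined with random
    single-edge perturbations accepted only when they improve the score.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    sc = BicScorer(data)
    nodes = sc.nodes
    if n_starts == 1:
        result = hill_climb(data, None, max_parents, seed, scorer=sc)
        counts = {e: 1 for e in result.edges()}
        parents = dict(result.parents)
    else:
        counts: dict[tuple[str, str], int] = {}
        for s in range(n_starts):
            start = random_dag(nodes, rng, max_parents=max_parents)
            res = hill_climb(data, start, max_parents, seed, scorer=sc)
            for e in res.edges():
                counts[e] = counts.get(e, 0) + 1
        majority = n_starts / 2.0
        parents = {v: set() for v in nodes}
        for (u, v), c in counts.items():
            if c > majority and counts.get((v, u), 0) <= majority:
                parents[v].add(u)
        parents = {v: frozenset(ps) for v, ps in parents.items()}
        parents = _break_cycles(parents, counts)
    model = sc.fit({v: frozenset(ps) for v, ps in parents.items()})
    # stochastic refinement: keep only score-improving perturbations
    for _ in range(refine_iters):
        u, v = rng.choice(nodes, size=2, replace=False)
        ps = model.parents[v]
        if u in ps:
            move = rng.choice(["delete", "reverse"])
            if move == "delete":
                cand = dict(model.parents)
                cand[v] = ps - {u}
            else:
                cand = dict(model.parents)
                cand[v] = ps - {u}
                if _has_path(cand, v, u) or len(model.parents[u]) >= max_parents:
                    continue
                cand[u] = model.parents[u] | {v}
        else:
            if len(ps) >= max_parents or _has_path(model.parents, u, v):
                continue
            cand = dict(model.parents)
            cand[v] = ps | {u}
        new_score = sc.total(cand)
        if new_score > model.score:
            model = sc.fit(cand)
    return model


@dataclass
class DriverScore:
    node: str
    delta_bic: float
    rank: int
    empirical_p: float = float("nan")


def _delta_bic(node: str, model: DAGModel, sc: BicScorer) -> float:
    """Network-score drop (over the other nodes) when ``node`` is removed."""
    delta = 0.0
    for child in model.children(node):
        with_g = sc.node_score(child, model.parents[child])
        without_g = sc.node_score(child, model.parents[child] - {node})
        delta += with_g - without_g
    return float(delta)


def driver_scores(model: DAGModel, data: pd.DataFrame,
                  scorer: BicScorer | None = None) -> list[DriverScore]:
    """Rank nodes by the BIC drop their removal causes (descending)."""
    sc = scorer or BicScorer(data[model.nodes])
    deltas = {g: _delta_bic(g, model, sc) for g in model.nodes}
    order = sorted(model.nodes, key=lambda g: -deltas[g])
    return [DriverScore(g, deltas[g], r + 1) for r, g in enumerate(order)]


def validate_driver(node: str, model: DAGModel, data: pd.DataFrame,
                    n_random: int = 5, iters: int = 1000, seed: int = 0,
                    candidates: list[str] | None = None,
                    scorer: BicScorer | None = None) -> float:
    """Empirical p of a driver's BIC drop against random non-candidate nodes.

    Per iteration, ``n_random`` random non-candidate nodes are scored; the p
    is (1 + #{iterations where max random drop >= driver drop}) / (iters+1).
    """
    if node not in model.nodes:
        raise ValueError(f"node {node!r} not in graph")
    sc = scorer or BicScorer(data[model.nodes])
    rng = np.random.default_rng(seed)
    cand = set(candidates or [node])
    pool = [g for g in model.nodes if g not in cand]
    if len(pool) < n_random:
        raise ValueError("not enough non-candidate nodes for the null")
    target = _delta_bic(node, model, sc)
    deltas = {g: _delta_bic(g, model, sc) for g in pool}
    exceed = 0
    for _ in range(iters):
        pick = rng.choice(pool, size=n_random, replace=False)
        if max(deltas[g] for g in pick) >= target:
            exceed += 1
    return float((1 + exceed) / (iters + 1))
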