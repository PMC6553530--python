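"""Gaussian Bayesian-network structure learning and model averaging.

Learns directed acyclic graphs over a small set of continuous variables
(here: kinship-decorrelated genetic values of latent factors) using

* decomposable network scores — the -2-rescaled BIC (penalized Gaussian
  log-likelihood, larger is better) and the BGe score (Gaussian -
  inverse-Wishart marginal likelihood, identical across members of a
  Markov equivalence class);
* Fisher-z partial-correlation tests of conditional independence;
* score-based search (steepest-ascent hill climbing and tabu search),
  a PC-style constraint-based skeleton with v-structure orientation and
  Meek rules, and two hybrid restrict-then-maximize learners (MMHC and
  a 2-phase restricted maximization);
* nonparametric bootstrap model averaging: arc strength = frequency of
  the arc across replicates, direction = orientation frequency given
  presence, with a strength threshold selecting the consensus graph.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import multigammaln
from scipy.stats import norm

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dag:
    """Directed acyclic graph stored as a parent map."""

    nodes: tuple[str, ...]
    parent_map: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        pm = {v: frozenset(self.parent_map.get(v, ())) for v in self.nodes}
        object.__setattr__(self, "parent_map", pm)
        for v, ps in pm.items():
            if v in ps:
                raise ValueError(f"self-loop at {v}")
            unknown = ps - set(self.nodes)
            if unknown:
                raise ValueError(f"unknown parents {unknown} of {v}")
        if self.topological_order() is None:
            raise ValueError("graph contains a cycle")

    @classmethod
    def from_edges(cls, nodes, edges) -> "Dag":
        pm: dict[str, set[str]] = {v: set() for v in nodes}
        for u, v in edges:
            pm[v].add(u)
        return cls(tuple(nodes), {v: frozenset(ps) for v, ps in pm.items()})

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset((p, v) for v in self.nodes for p in self.parent_map[v])

    def parents(self, v: str) -> frozenset[str]:
        return self.parent_map[v]

    def topological_order(self) -> list[str] | None:
        placed: set[str] = set()
        order: list[str] = []
        pending = list(self.nodes)
        while pending:
            ready = [v for v in pending if self.parent_map.get(v, frozenset()) <= placed]
            if not ready:
                return None
            order.extend(ready)
            placed.update(ready)
            pending = [v for v in pending if v not in placed]
        return order

    def has_path(self, src: str, dst: str) -> bool:
        """True if a directed path src -> ... -> dst exists."""
        children: dict[str, list[str]] = {v: [] for v in self.nodes}
        for p, c in self.edges:
            children[p].append(c)
        stack, seen = [src], set()
        while stack:
            v = stack.pop()
            if v == dst:
                return True
            if v in seen:
                continue
            seen.add(v)
            stack.extend(children[v])
        return False

    def with_parents(self, node: str, parents: frozenset[str]) -> "Dag":
        pm = dict(self.parent_map)
        pm[node] = frozenset(parents)
        return Dag(self.nodes, pm)

    def adjacencies(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.edges)


@dataclass(frozen=True)
class Cpdag:
    """Pattern of a Markov equivalence class: compelled edges directed,
    reversible edges undirected."""

    nodes: tuple[str, ...]
    directed_edges: frozenset[tuple[str, str]]
    undirected_edges: frozenset[frozenset[str]]

    def adjacencies(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.directed_edges) | self.undirected_edges


def enumerate_dags(nodes: tuple[str, ...]):
    """Yield every DAG on ``nodes`` (25 for 3 nodes, 543 for 4)."""
    pairs = list(itertools.combinations(nodes, 2))
    for choice in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (u, v), c in zip(pairs, choice):
            if c == 1:
                edges.append((u, v))
            elif c == 2:
                edges.append((v, u))
        try:
            yield Dag.from_edges(nodes, edges)
        except ValueError:
            continue


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------


@dataclass
class ScoreConfig:
    score_tag: str = "bic"  # "bic" or "bge"
    bge_iss_mu: float = 1.0
    bge_iss_w: float | None = None  # default q + 2
    bge_prior_mean: np.ndarray | None = None  # default sample mean
    bge_prior_scale: np.ndarray | None = None  # default identity-scaled


class BicScore:
    """-2-rescaled BIC: sum over nodes of max Gaussian log-likelihood of
    the node given its parents minus (|Pa| + 2)/2 log n (intercept,
    coefficients and residual variance all count as parameters).
    Decomposable; larger is better."""

    tag = "bic"

    def __init__(self, data: pd.DataFrame):
        self.columns = list(data.columns)
        self.X = data.to_numpy(float)
        self.n = self.X.shape[0]
        self._idx = {c: i for i, c in enumerate(self.columns)}
        self._cache: dict[tuple[str, frozenset[str]], float] = {}

    def local(self, node: str, parents: frozenset[str]) -> float:
        key = (node, parents)
        if key in self._cache:
            return self._cache[key]
        n = self.n
        if len(parents) >= n - 1:
            raise ValueError(f"node {node}: {len(parents)} parents for n={n} rows")
        y = self.X[:, self._idx[node]]
        Z = np.column_stack(
            [np.ones(n)] + [self.X[:, self._idx[p]] for p in sorted(parents)]
        )
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        rss = float(np.sum((y - Z @ beta) ** 2))
        sigma2 = max(rss / n, 1e-300)
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        val = loglik - 0.5 * (len(parents) + 2) * np.log(n)
        self._cache[key] = val
        return val

    def total(self, dag: Dag) -> float:
        return sum(self.local(v, dag.parents(v)) for v in dag.nodes)


class BgeScore:
    """Bayesian Gaussian equivalent score.

    Log marginal likelihood of the data under the conjugate
    normal - Wishart family, computed node-wise as
    log m(v u Pa(v)) - log m(Pa(v)) with the dimension-adjusted degrees
    of freedom that make the score identical across Markov-equivalent
    DAGs.  Hyperparameters: equivalent sample sizes alpha_mu (mean) and
    alpha_w (precision, default q + 2), prior mean nu (default sample
    mean) and prior scale T (default t * I with
    t = alpha_mu (alpha_w - q - 1) / (alpha_mu + 1))."""

    tag = "bge"

    def __init__(self, data: pd.DataFrame, cfg: ScoreConfig | None = None):
        cfg = cfg or ScoreConfig(score_tag="bge")
        self.columns = list(data.columns)
        X = data.to_numpy(float)
        self.n, q = X.shape
        self.q = q
        self.a_mu = float(cfg.bge_iss_mu)
        self.a_w = float(cfg.bge_iss_w) if cfg.bge_iss_w is not None else q + 2.0
        if self.a_mu <= 0 or self.a_w <= q - 1:
            raise ValueError("equivalent sample sizes must be positive (a_w > q - 1)")
        nu = (
            np.asarray(cfg.bge_prior_mean, float)
            if cfg.bge_prior_mean is not None
            else X.mean(axis=0)
        )
        if cfg.bge_prior_scale is not None:
            T0 = np.asarray(cfg.bge_prior_scale, float)
        else:
            t = self.a_mu * (self.a_w - q - 1.0) / (self.a_mu + 1.0)
            if t <= 0:
                raise ValueError("degenerate default prior scale: need a_w > q + 1")
            T0 = t * np.eye(q)
        if np.any(np.linalg.eigvalsh(0.5 * (T0 + T0.T)) <= 0):
            raise ValueError("degenerate prior scale matrix (not positive definite)")
        xbar = X.mean(axis=0)
        Xc = X - xbar
        S = Xc.T @ Xc
        shift = nu - xbar
        self.R = T0 + S + (self.n * self.a_mu / (self.n + self.a_mu)) * np.outer(shift, shift)
        self.T0 = T0
        self._idx = {c: i for i, c in enumerate(self.columns)}
        self._ml_cache: dict[frozenset[str], float] = {}
        self._cache: dict[tuple[str, frozenset[str]], float] = {}

    def _log_marginal(self, subset: frozenset[str]) -> float:
        if not subset:
            return 0.0
        if subset in self._ml_cache:
            return self._ml_cache[subset]
        idx = sorted(self._idx[c] for c in subset)
        l = len(idx)
        n, q, a_mu, a_w = self.n, self.q, self.a_mu, self.a_w
        sign_t, logdet_t = np.linalg.slogdet(self.T0[np.ix_(idx, idx)])
        sign_r, logdet_r = np.linalg.slogdet(self.R[np.ix_(idx, idx)])
        if sign_t <= 0 or sign_r <= 0:
            raise ValueError("degenerate prior scale or posterior scatter submatrix")
        val = (
            0.5 * l * np.log(a_mu / (n + a_mu))
            - 0.5 * n * l * np.log(np.pi)
            + multigammaln(0.5 * (n + a_w - q + l), l)
            - multigammaln(0.5 * (a_w - q + l), l)
            + 0.5 * (a_w - q + l) * logdet_t
            - 0.5 * (n + a_w - q + l) * logdet_r
        )
        self._ml_cache[subset] = val
        return val

    def local(self, node: str, parents: frozenset[str]) -> float:
        key = (node, parents)
        if key not in self._cache:
            self._cache[key] = self._log_marginal(parents | {node}) - self._log_marginal(
                parents
            )
        return self._cache[key]

    def total(self, dag: Dag) -> float:
        return sum(self.local(v, dag.parents(v)) for v in dag.nodes)


def make_score(data: pd.DataFrame, cfg: ScoreConfig | str | None = None):
    if cfg is None:
        cfg = ScoreConfig()
    if isinstance(cfg, str):
        cfg = ScoreConfig(score_tag=cfg)
    if cfg.score_tag == "bic":
        return BicScore(data)
    if cfg.score_tag == "bge":
        return BgeScore(data, cfg)
    raise ValueError(f"unknown score {cfg.score_tag!r}")


def score_bic(data: pd.DataFrame, dag: Dag) -> float:
    return BicScore(data).total(dag)


def score_bge(data: pd.DataFrame, dag: Dag, cfg: ScoreConfig | None = None) -> float:
    return BgeScore(data, cfg).total(dag)


# ---------------------------------------------------------------------------
# conditional independence
# ---------------------------------------------------------------------------


def ci_test_fisher_z(
    data: pd.DataFrame, x: str, y: str, conditioning_set: tuple[str, ...] = ()
) -> float:
    """Two-sided p-value of partial correlation(x, y | S) via Fisher's z.

    The partial correlation is read off the inverse of the correlation
    submatrix of {x, y} u S; z = atanh(r) sqrt(n - |S| - 3)."""
    S = tuple(conditioning_set)
    n = len(data)
    dof = n - len(S) - 3
    if dof <= 0:
        raise ValueError(f"need n - |S| - 3 > 0 (n={n}, |S|={len(S)})")
    cols = [x, y, *S]
    C = np.corrcoef(data[cols].to_numpy(float), rowvar=False)
    C = np.atleast_2d(C)
    try:
        P = np.linalg.inv(C)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular correlation submatrix for ({x}, {y} | {S})"
        ) from err
    r = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
    r = float(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    z = np.arctanh(r) * np.sqrt(dof)
    return float(2.0 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# score-based search
# ---------------------------------------------------------------------------


def _legal_moves(dag: Dag, allowed: frozenset[frozenset[str]] | None):
    """Yield (kind, u, v) for every acyclicity-preserving add/delete/reverse."""
    edges = dag.edges
    adjacent = {frozenset(e) for e in edges}
    for u, v in itertools.permutations(dag.nodes, 2):
        pair = frozenset((u, v))
        if (u, v) in edges:
            yield ("delete", u, v)
            if not dag.with_parents(v, dag.parents(v) - {u}).has_path(u, v):
                yield ("reverse", u, v)
        elif pair not in adjacent:
            if allowed is not None and pair not in allowed:
                continue
            if not dag.has_path(v, u):
                yield ("add", u, v)


def _move_delta(dag: Dag, scorer, kind: str, u: str, v: str) -> float:
    pv = dag.parents(v)
    if kind == "add":
        return scorer.local(v, pv | {u}) - scorer.local(v, pv)
    if kind == "delete":
        return scorer.local(v, pv - {u}) - scorer.local(v, pv)
    pu = dag.parents(u)
    return (
        scorer.local(v, pv - {u})
        - scorer.local(v, pv)
        + scorer.local(u, pu | {v})
        - scorer.local(u, pu)
    )


def _apply_move(dag: Dag, kind: str, u: str, v: str) -> Dag:
    if kind == "add":
        return dag.with_parents(v, dag.parents(v) | {u})
    if kind == "delete":
        return dag.with_parents(v, dag.parents(v) - {u})
    return dag.with_parents(v, dag.parents(v) - {u}).with_parents(
        u, dag.parents(u) | {v}
    )


_TIE_TOL = 1e-9


def _best_move(dag: Dag, scorer, allowed) -> tuple[float, str, str, str] | None:
    """Steepest move with equivalence-aware tie resolution.

    With score-equivalent Gaussian scores, the two orientations of a
    freshly added arc score identically, so a naive steepest ascent
    commits to an arbitrary orientation and can lock itself out of
    collider configurations.  Exact ties among the best moves are
    therefore broken by a one-step lookahead (the tied move whose
    successor graph admits the largest further improvement wins);
    remaining ties fall back to a fixed lexicographic order, keeping the
    search fully deterministic.
    """
    moves = [
        (_move_delta(dag, scorer, k, u, v), k, u, v)
        for k, u, v in _legal_moves(dag, allowed)
    ]
    if not moves:
        return None
    top = max(m[0] for m in moves)
    tied = sorted((m for m in moves if m[0] >= top - _TIE_TOL), key=lambda m: m[1:])
    if len(tied) == 1:
        return tied[0]
    best, best_key = None, None
    for mv in tied:
        nxt = _apply_move(dag, *mv[1:])
        followups = [
            _move_delta(nxt, scorer, k, u, v) for k, u, v in _legal_moves(nxt, allowed)
        ]
        key = max(followups, default=0.0)
        if best_key is None or key > best_key + _TIE_TOL:
            best, best_key = mv, key
    return best


def learn_hc(
    data: pd.DataFrame,
    score: ScoreConfig | str | None = None,
    seed: int | None = None,
    allowed: frozenset[frozenset[str]] | None = None,
    scorer=None,
) -> Dag:
    """Steepest-ascent hill climbing from the empty graph.

    At every step the single add/delete/reverse move with the largest
    positive score improvement is applied (exact ties resolved by a
    deterministic one-step lookahead); search stops when no move
    improves.  ``allowed`` optionally restricts additions to a whitelist
    of adjacencies (used by the hybrid learners).  ``seed`` is accepted
    for interface uniformity; the search is deterministic with zero
    random restarts.
    """
    scorer = scorer or make_score(data, score)
    dag = Dag.from_edges(tuple(data.columns), [])
    while True:
        best = _best_move(dag, scorer, allowed)
        if best is None or best[0] <= 1e-10:
            return dag
        dag = _apply_move(dag, *best[1:])


def learn_tabu(
    data: pd.DataFrame,
    score: ScoreConfig | str | None = None,
    tabu_len: int = 10,
    max_stale: int | None = None,
    seed: int | None = None,
    allowed: frozenset[frozenset[str]] | None = None,
    scorer=None,
) -> Dag:
    """Tabu search: hill climbing that may accept the best non-improving
    move while keeping a list of recently visited graphs forbidden, and
    returns the best network seen.  ``max_stale`` non-improving steps are
    allowed (default 2 q^2)."""
    scorer = scorer or make_score(data, score)
    q = data.shape[1]
    if max_stale is None:
        max_stale = 2 * q * q
    dag = Dag.from_edges(tuple(data.columns), [])
    current_score = scorer.total(dag)
    best_dag, best_score = dag, current_score
    tabu: deque[frozenset] = deque(maxlen=max(tabu_len, 1))
    tabu.append(dag.edges)
    stale = 0
    while stale <= max_stale:
        moves = [
            (_move_delta(dag, scorer, k, u, v), k, u, v)
            for k, u, v in _legal_moves(dag, allowed)
            if _apply_move(dag, k, u, v).edges not in tabu
        ]
        if not moves:
            break
        top = max(m[0] for m in moves)
        tied = sorted((m for m in moves if m[0] >= top - _TIE_TOL), key=lambda m: m[1:])
        best_move = tied[0]
        if len(tied) > 1:
            best_key = None
            for mv in tied:
                nxt = _apply_move(dag, *mv[1:])
                key = max(
                    (_move_delta(nxt, scorer, k, u, v) for k, u, v in _legal_moves(nxt, allowed)),
                    default=0.0,
                )
                if best_key is None or key > best_key + _TIE_TOL:
                    best_move, best_key = mv, key
        dag = _apply_move(dag, *best_move[1:])
        current_score += best_move[0]
        tabu.append(dag.edges)
        if current_score > best_score + 1e-10:
            best_dag, best_score = dag, current_score
            stale = 0
        else:
            stale += 1
    return best_dag


# ---------------------------------------------------------------------------
# constraint-based machinery: PC skeleton, v-structures, Meek rules
# ---------------------------------------------------------------------------


def _meek_closure(
    nodes: tuple[str, ...],
    directed: set[tuple[str, str]],
    undirected: set[frozenset[str]],
) -> None:
    """Orient compelled edges in place using Meek rules R1-R3.

    R4 is only required when extra orientations come from background
    knowledge, which never happens here.
    """

    def adjacent(a, b):
        return (
            frozenset((a, b)) in undirected or (a, b) in directed or (b, a) in directed
        )

    changed = True
    while changed:
        changed = False
        for pair in list(undirected):
            a, b = tuple(pair)
            for x, y in ((a, b), (b, a)):
                # R1: c -> x, x - y, c and y non-adjacent  =>  x -> y
                if any(
                    (c, x) in directed and not adjacent(c, y)
                    for c in nodes
                    if c not in (x, y)
                ):
                    undirected.discard(pair)
                    directed.add((x, y))
                    changed = True
                    break
                # R2: x -> c -> y with x - y  =>  x -> y
                if any(
                    (x, c) in directed and (c, y) in directed
                    for c in nodes
                    if c not in (x, y)
                ):
                    undirected.discard(pair)
                    directed.add((x, y))
                    changed = True
                    break
                # R3: x - c, x - d, c -> y, d -> y, c and d non-adjacent => x -> y
                nbrs = [
                    c
                    for c in nodes
                    if c not in (x, y)
                    and frozenset((x, c)) in undirected
                    and (c, y) in directed
                ]
                if any(
                    not adjacent(c, d) for c, d in itertools.combinations(nbrs, 2)
                ):
                    undirected.discard(pair)
                    directed.add((x, y))
                    changed = True
                    break
            if changed:
                break


def learn_skeleton(
    data: pd.DataFrame, alpha: float = 0.05, max_cond: int | None = None
) -> Cpdag:
    """PC-style constraint-based pattern learning.

    Removes edges for which some conditioning set renders the pair
    independent (Fisher-z test at level ``alpha``), searching conditioning
    sets of increasing size within current neighborhoods; orients
    v-structures a -> c <- b for non-adjacent a, b whose separating set
    excludes c; closes under Meek rules.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    nodes = tuple(data.columns)
    adj: dict[str, set[str]] = {v: set(nodes) - {v} for v in nodes}
    sepset: dict[frozenset[str], frozenset[str]] = {}
    level = 0
    limit = max_cond if max_cond is not None else len(nodes) - 2
    while level <= limit:
        frozen = {v: set(adj[v]) for v in nodes}
        any_testable = False
        for x in nodes:
            for y in sorted(frozen[x]):
                if y not in adj[x]:
                    continue
                cands = frozen[x] - {y}
                if len(cands) < level:
                    continue
                any_testable = True
                for S in itertools.combinations(sorted(cands), level):
                    if ci_test_fisher_z(data, x, y, S) > alpha:
                        adj[x].discard(y)
                        adj[y].discard(x)
                        sepset[frozenset((x, y))] = frozenset(S)
                        break
        if not any_testable:
            break
        level += 1
    undirected = {frozenset((x, y)) for x in nodes for y in adj[x]}
    directed: set[tuple[str, str]] = set()
    # v-structures
    for a, b in itertools.combinations(nodes, 2):
        if b in adj[a]:
            continue
        S = sepset.get(frozenset((a, b)), frozenset())
        for c in sorted(adj[a] & adj[b]):
            if c not in S:
                for edge in (frozenset((a, c)), frozenset((b, c))):
                    undirected.discard(edge)
                directed.update({(a, c), (b, c)})
                directed.discard((c, a))
                directed.discard((c, b))
    _meek_closure(nodes, directed, undirected)
    return Cpdag(nodes, frozenset(directed), frozenset(undirected))


def cpdag_of(dag: Dag) -> Cpdag:
    """Pattern (CPDAG) of the Markov equivalence class containing ``dag``:
    skeleton + v-structures, closed under Meek rules."""
    nodes = dag.nodes
    edges = dag.edges
    adjacent = {frozenset(e) for e in edges}
    undirected = set(adjacent)
    directed: set[tuple[str, str]] = set()
    for v in nodes:
        for a, b in itertools.combinations(sorted(dag.parents(v)), 2):
            if frozenset((a, b)) not in adjacent:
                for edge in (frozenset((a, v)), frozenset((b, v))):
                    undirected.discard(edge)
                directed.update({(a, v), (b, v)})
    _meek_closure(nodes, directed, undirected)
    return Cpdag(nodes, frozenset(directed), frozenset(undirected))


# ---------------------------------------------------------------------------
# hybrid learners
# ---------------------------------------------------------------------------


def _subsets(items, max_size=None):
    items = sorted(items)
    top = len(items) if max_size is None else min(max_size, len(items))
    for k in range(top + 1):
        yield from itertools.combinations(items, k)


def _mmpc_one(data: pd.DataFrame, target: str, alpha: float) -> set[str]:
    """Max-Min Parents-Children candidate set for one node: forward
    max-min association growth, then backward subset elimination."""
    others = [c for c in data.columns if c != target]
    cpc: list[str] = []
    while True:
        best_var, best_p = None, None
        for x in others:
            if x in cpc:
                continue
            # min association over subsets = max p-value
            p_max = max(
                ci_test_fisher_z(data, target, x, S) for S in _subsets(cpc)
            )
            if best_p is None or p_max < best_p:
                best_var, best_p = x, p_max
        if best_var is None or best_p >= alpha:
            break
        cpc.append(best_var)
    # backward: drop members separated by some subset of the others
    for x in list(cpc):
        rest = [c for c in cpc if c != x]
        if any(ci_test_fisher_z(data, target, x, S) >= alpha for S in _subsets(rest)):
            cpc.remove(x)
    return set(cpc)


def _hiton_pc_one(data: pd.DataFrame, target: str, alpha: float) -> set[str]:
    """Interleaved HITON-PC-style selection: admit candidates by marginal
    association strength, eliminating any candidate separated given a
    subset of the current set."""
    marg = {
        x: ci_test_fisher_z(data, target, x) for x in data.columns if x != target
    }
    queue = [x for x in sorted(marg, key=lambda k: marg[k]) if marg[x] < alpha]
    cpc: list[str] = []
    for x in queue:
        cpc.append(x)
        for y in list(cpc):
            rest = [c for c in cpc if c != y]
            if any(
                ci_test_fisher_z(data, target, y, S) >= alpha for S in _subsets(rest)
            ):
                cpc.remove(y)
    return set(cpc)


def restrict_phase(
    data: pd.DataFrame, method: str = "mmpc", alpha: float = 0.05
) -> frozenset[frozenset[str]]:
    """Per-node candidate neighbor sets, symmetrized by intersection."""
    fn = {"mmpc": _mmpc_one, "hiton": _hiton_pc_one}[method]
    pc = {v: fn(data, v, alpha) for v in data.columns}
    allowed = {
        frozenset((x, y))
        for x in data.columns
        for y in pc[x]
        if x in pc[y]
    }
    return frozenset(allowed)


def learn_hybrid(
    data: pd.DataFrame,
    variant_tag: str = "mmhc",
    alpha: float = 0.05,
    score: ScoreConfig | str | None = None,
    seed: int | None = None,
) -> Dag:
    """Restrict-then-maximize hybrid learning.

    ``mmhc`` restricts with Max-Min Parents-Children; ``rsmax2`` (2-phase
    restricted maximization) restricts with the HITON-PC-style selector.
    Both maximize by hill climbing confined to the restricted arcs, so
    the result can only contain whitelisted adjacencies.
    """
    if variant_tag not in ("mmhc", "rsmax2"):
        raise ValueError(f"unknown hybrid variant {variant_tag!r}")
    method = "mmpc" if variant_tag == "mmhc" else "hiton"
    allowed = restrict_phase(data, method=method, alpha=alpha)
    return learn_hc(data, score=score, seed=seed, allowed=allowed)


# ---------------------------------------------------------------------------
# bootstrap model averaging
# ---------------------------------------------------------------------------


@dataclass
class AveragedNetwork:
    arc_strength: dict[frozenset[str], float]
    arc_direction: dict[tuple[str, str], float]
    strength_threshold: float
    direction_threshold: float
    consensus: Dag
    scores: dict[str, float]
    n_boot: int
    n_redrawn: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Arc table: one row per consensus-orientable direction of every
        arc seen in any replicate."""
        rows = []
        for pair, s in sorted(self.arc_strength.items(), key=lambda kv: -kv[1]):
            a, b = sorted(pair)
            for u, v in ((a, b), (b, a)):
                rows.append(
                    {
                        "from": u,
                        "to": v,
                        "strength": s,
                        "direction": self.arc_direction.get((u, v), 0.0),
                    }
                )
        return pd.DataFrame(rows, columns=["from", "to", "strength", "direction"])


def _resolve_cycles(
    edges: list[tuple[str, str]],
    nodes: tuple[str, ...],
    strength: dict[frozenset[str], float],
) -> Dag:
    """Drop the weakest arc of any remaining cycle until acyclic."""
    current = list(edges)
    while True:
        try:
            return Dag.from_edges(nodes, current)
        except ValueError:
            weakest = min(current, key=lambda e: (strength[frozenset(e)], e))
            warnings.warn(
                f"consensus cycle: dropping weakest arc {weakest} "
                f"(strength {strength[frozenset(weakest)]:.3f})"
            )
            current.remove(weakest)


def bootstrap_average(
    data: pd.DataFrame,
    learner,
    n_boot: int = 500,
    strength_threshold: float = 0.85,
    direction_threshold: float = 0.5,
    seed: int = 0,
) -> AveragedNetwork:
    """Nonparametric bootstrap model averaging of learned structures.

    Resamples accessions with replacement (replicate size = n), learns
    one DAG per replicate with ``learner(dataframe)``, and tallies arc
    strength (presence frequency in either direction) and direction
    (orientation frequency conditional on presence).  The consensus
    keeps arcs with strength >= threshold, oriented by majority
    direction (ties broken toward the lexicographically smaller ordered
    pair, logged); a cyclic consensus is repaired by dropping the
    weakest arc in the cycle, with a warning.  Replicates in which some
    column degenerates to zero variance are redrawn and counted.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not (0 < strength_threshold <= 1 and 0 < direction_threshold <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(data)
    nodes = tuple(data.columns)
    pair_counts: dict[frozenset[str], int] = {}
    dir_counts: dict[tuple[str, str], int] = {}
    n_redrawn = 0
    for _ in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            boot = data.iloc[idx].reset_index(drop=True)
            if (boot.std(ddof=0) > 0).all():
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap replicate")
        dag = learner(boot)
        for u, v in dag.edges:
            pair = frozenset((u, v))
            pair_counts[pair] = pair_counts.get(pair, 0) + 1
            dir_counts[(u, v)] = dir_counts.get((u, v), 0) + 1
    if n_redrawn:
        logger.info("redrew %d degenerate bootstrap replicates", n_redrawn)
    strength = {p: c / n_boot for p, c in pair_counts.items()}
    direction = {}
    for pair, c in pair_counts.items():
        a, b = sorted(pair)
        direction[(a, b)] = dir_counts.get((a, b), 0) / c
        direction[(b, a)] = dir_counts.get((b, a), 0) / c
    consensus_edges = []
    for pair, s in strength.items():
        if s < strength_threshold:
            continue
        a, b = sorted(pair)
        if direction[(a, b)] > direction[(b, a)]:
            consensus_edges.append((a, b))
        elif direction[(b, a)] > direction[(a, b)]:
            consensus_edges.append((b, a))
        else:
            logger.info("direction tie for %s-%s; keeping %s -> %s", a, b, a, b)
            consensus_edges.append((a, b))
    consensus_edges = [
        e for e in consensus_edges if direction[e] >= direction_threshold
    ] + [e for e in consensus_edges if direction[e] < direction_threshold]
    consensus = _resolve_cycles(consensus_edges, nodes, strength)
    scores = {
        "bic": BicScore(data).total(consensus),
        "bge": BgeScore(data).total(consensus),
    }
    return AveragedNetwork(
        arc_strength=strength,
        arc_direction=direction,
        strength_threshold=strength_threshold,
        direction_threshold=direction_threshold,
        consensus=consensus,
        scores=scores,
        n_boot=n_boot,
        n_redrawn=n_redrawn,
    )


def make_learner(
    algorithm: str,
    score: ScoreConfig | str | None = None,
    alpha: float = 0.05,
    tabu_len: int = 10,
):
    """Callable ``f(dataframe) -> Dag`` for one of the four algorithms:
    hc, tabu, mmhc, rsmax2."""
    if algorithm == "hc":
        return lambda df: learn_hc(df, score=score)
    if algorithm == "tabu":
        return lambda df: learn_tabu(df, score=score, tabu_len=tabu_len)
    if algorithm in ("mmhc", "rsmax2"):
        return lambda df: learn_hybrid(df, variant_tag=algorithm, alpha=alpha, score=score)
    raise ValueError(f"unknown algorithm {algorithm!r}")


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def to_networkx(dag: Dag):
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    g.add_edges_from(sorted(dag.edges))
    return g


def write_dot(dag: Dag, path, averaged: AveragedNetwork | None = None) -> None:
    lines = ["digraph consensus {"]
    for v in dag.nodes:
        lines.append(f'  "{v}";')
    for u, v in sorted(dag.edges):
        label = ""
        if averaged is not None:
            s = averaged.arc_strength.get(frozenset((u, v)), float("nan"))
            d = averaged.arc_direction.get((u, v), float("nan"))
            label = f' [label="{s:.2f} ({d:.2f})"]'
        lines.append(f'  "{u}" -> "{v}"{label};')
    lines.append("}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def write_graphml(dag: Dag, path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(dag), path)
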