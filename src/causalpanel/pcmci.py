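"""PCMCI+-style causal discovery for daily panels.

Three stages, composed by :func:`run_pcmciplus`:

1. :func:`discover_skeleton` — PC-stable search over all candidate links
   ``X_{t-tau}^i -> X_t^j`` (``tau = 0..tau_max``, no lag-0 self-links).
   At conditioning-set size ``s`` each remaining link is tested given the
   ``s`` strongest current parents of its sink (strength = ``|rho|`` from
   the previous level); contemporaneous candidates are additionally
   conditioned on the strongest discovered lagged parents of the source.
   Adjacencies are frozen within a level (stable variant) and separating
   sets are recorded for orientation.
2. :func:`orient_links` — lagged links point past -> present; unshielded
   contemporaneous triples are oriented by the collider rule, followed by
   Meek propagation; contradictory rules mark a link ``conflict``.
3. :func:`mci_validate` — every surviving link is re-tested conditioning on
   the lagged parents of its sink *and* the time-shifted lagged parents of
   its source (the momentary-conditional-independence test, which controls
   the false positives that autocorrelation otherwise inflates).  Links
   with ``p > alpha`` are dropped; the final graph carries the MCI ``rho``
   and p-value per link.

All tests within one run share a single row alignment (rows
``t = 2*tau_max .. T-1``), so every p-value is computed on the same
effective sample; the doubled margin leaves room for the MCI stage's
time-shifted conditioning columns.  The engine has no internal randomness:
identical panel and parameters give an identical graph.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .citest import _residual_corr, _rho_to_p
from .graphs import CausalGraph, CausalLink
from .panel import TimeSeriesPanel

__all__ = ["Skeleton", "discover_skeleton", "orient_links", "mci_validate", "run_pcmciplus"]

Var = tuple[int, int]  # (variable index, lag)


def _lagged_design(values: np.ndarray, max_lag: int) -> np.ndarray:
    """Columns ``X_{t-tau}^i`` for rows ``t = max_lag..T-1``; col = i*(L+1)+tau."""
    T, n = values.shape
    n_eff = T - max_lag
    if n_eff < 3:
        raise ValueError("series too short for the requested maximum lag")
    design = np.empty((n_eff, n * (max_lag + 1)))
    for i in range(n):
        for tau in range(max_lag + 1):
            design[:, i * (max_lag + 1) + tau] = values[max_lag - tau: T - tau, i]
    return design


@dataclass
class Skeleton:
    """Adjacency sets plus the separating-set and test records behind them."""

    n_vars: int
    tau_max: int
    alpha: float
    adjacency: dict[int, set[Var]]
    sepsets: dict[tuple[int, int, int], list[Var]]
    stats: dict[tuple[int, int, int], tuple[float, float]]
    n_eff: int
    names: list[str] | None = None


class _Tester:
    """Shared aligned design + ParCorr evaluation on column labels."""

    def __init__(self, values: np.ndarray, tau_max: int):
        self.tau_max = tau_max
        self.max_lag = 2 * tau_max
        self.design = _lagged_design(values, self.max_lag)
        self.n_eff = self.design.shape[0]
        self._width = self.max_lag + 1

    def col(self, var: Var) -> np.ndarray:
        i, tau = var
        return self.design[:, i * self._width + tau]

    def test(self, x: Var, y: Var, cond: list[Var]) -> tuple[float, float]:
        Z = None
        if cond:
            Z = np.column_stack([self.col(v) for v in cond])
        rho, dof = _residual_corr(self.col(x), self.col(y), Z)
        return rho, _rho_to_p(rho, dof)


def _candidate_parents(n_vars: int, tau_max: int, j: int) -> set[Var]:
    cands = {(i, tau) for i in range(n_vars) for tau in range(1, tau_max + 1)}
    cands |= {(i, 0) for i in range(n_vars) if i != j}
    return cands


def discover_skeleton(
    panel: TimeSeriesPanel | np.ndarray,
    tau_max: int,
    alpha: float,
    _tester: _Tester | None = None,
) -> Skeleton:
    """PC-stable skeleton search; see the module docstring for the rules.

    ``alpha`` here is the condition-selection level: a link is removed as
    soon as a test at some level yields ``p > alpha``.  Because surviving
    links are retested at every level (and again by MCI), running the
    skeleton at the final decision level would prune well below it; the
    full engine therefore runs the skeleton at a laxer ``pc_alpha`` and
    leaves the level-``alpha`` decision to the MCI stage.
    """
    values, names = _as_values(panel)
    T, n_vars = values.shape
    if T <= (tau_max + 2) * n_vars:
        raise ValueError("sample too short for tau_max")
    tester = _tester or _Tester(values, tau_max)
    adjacency = {j: _candidate_parents(n_vars, tau_max, j) for j in range(n_vars)}
    strength: dict[tuple[int, int, int], float] = {}
    sepsets: dict[tuple[int, int, int], list[Var]] = {}
    stats: dict[tuple[int, int, int], tuple[float, float]] = {}

    def rank_key(parent: Var, sink: int) -> tuple:
        return (-strength.get((parent[0], parent[1], sink), np.inf), parent[0], parent[1])

    s = 0
    while True:
        tested_any = False
        removals: list[tuple[int, Var]] = []
        for j in range(n_vars):
            for (i, tau) in sorted(adjacency[j]):
                others = adjacency[j] - {(i, tau)}
                if len(others) < s:
                    continue
                tested_any = True
                cond = sorted(others, key=lambda v: rank_key(v, j))[:s]
                if tau == 0 and s > 0:
                    lagged_src = [(k, t) for (k, t) in adjacency[i] if t >= 1]
                    lagged_src.sort(key=lambda v: rank_key(v, i))
                    for extra in lagged_src[:s]:
                        if extra not in cond:
                            cond.append(extra)
                rho, p = tester.test((i, tau), (j, 0), cond)
                stats[(i, tau, j)] = (rho, p)
                strength[(i, tau, j)] = abs(rho)
                if p > alpha:
                    removals.append((j, (i, tau)))
                    sepsets[(i, tau, j)] = list(cond)
        for j, (i, tau) in removals:  # frozen within the level (PC-stable)
            adjacency[j].discard((i, tau))
            if tau == 0:
                adjacency[i].discard((j, 0))
        if not tested_any:
            break
        s += 1
    return Skeleton(
        n_vars=n_vars,
        tau_max=tau_max,
        alpha=alpha,
        adjacency=adjacency,
        sepsets=sepsets,
        stats=stats,
        n_eff=tester.n_eff,
        names=names,
    )


def _as_values(panel) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(panel, TimeSeriesPanel):
        return panel.values, list(panel.names)
    return np.asarray(panel, dtype=float), None


def _orient_pairs(n: int, pairs: set[tuple[int, int]], sepset) -> tuple[dict, set, set]:
    """Collider rule + Meek propagation on a set of contemporaneous pairs.

    ``sepset(a, b)`` must return the separating set recorded when the
    (non-adjacent) pair ``a, b`` was removed.  Returns
    ``(directed, conflict, undirected)``.
    """

    def adjacent(a: int, b: int) -> bool:
        return (min(a, b), max(a, b)) in pairs

    directed: dict[tuple[int, int], tuple[int, int]] = {}
    conflict: set[tuple[int, int]] = set()
    undirected = set(pairs)

    # collider rule on unshielded contemporaneous triples
    proposals: dict[tuple[int, int], set[tuple[int, int]]] = {}
    for k in range(n):
        nbrs = sorted(v for v in range(n) if v != k and adjacent(v, k))
        for a, b in combinations(nbrs, 2):
            if adjacent(a, b):
                continue
            if (k, 0) not in sepset(a, b):
                for src in (a, b):
                    pair = (min(src, k), max(src, k))
                    proposals.setdefault(pair, set()).add((src, k))
    for pair, props in proposals.items():
        if len(props) > 1:
            conflict.add(pair)
        else:
            directed[pair] = next(iter(props))
        undirected.discard(pair)

    def orient(src: int, snk: int) -> bool:
        pair = (min(src, snk), max(src, snk))
        if pair in conflict or pair not in undirected:
            return False
        directed[pair] = (src, snk)
        undirected.discard(pair)
        return True

    changed = True
    while changed:  # Meek propagation R1-R3
        changed = False
        arrows = list(directed.values())
        for a, b in arrows:
            for c in range(n):
                if c in (a, b):
                    continue
                if (min(b, c), max(b, c)) in undirected and not adjacent(a, c):
                    changed |= orient(b, c)  # R1
        # R2: a -> b -> c with a — c undirected orients a -> c
        arrow_set = set(directed.values())
        for a, b in list(arrow_set):
            for b2, c in list(arrow_set):
                if b2 != b or c == a:
                    continue
                if (min(a, c), max(a, c)) in undirected:
                    changed |= orient(a, c)
        # R3: a — b with a — c, a — d, c -> b, d -> b, c/d nonadjacent orients a -> b
        for pair in sorted(undirected):
            for a, b in (pair, pair[::-1]):
                into_b = [s for (s, t) in arrow_set if t == b and s != a]
                hit = False
                for c, d in combinations(sorted(into_b), 2):
                    if adjacent(a, c) and adjacent(a, d) and not adjacent(c, d):
                        hit = True
                        break
                if hit:
                    changed |= orient(a, b)
                    break
        arrow_set = set(directed.values())

    return directed, conflict, undirected


def _skeleton_sepset(skeleton: Skeleton, a: int, b: int) -> list[Var]:
    return skeleton.sepsets.get((a, 0, b)) or skeleton.sepsets.get((b, 0, a)) or []


def orient_links(skeleton: Skeleton) -> CausalGraph:
    """Orient the skeleton: time order, then collider rule, then Meek rules."""
    n = skeleton.n_vars
    links: list[CausalLink] = []
    for j in range(n):
        for (i, tau) in sorted(skeleton.adjacency[j]):
            if tau >= 1:
                rho, p = skeleton.stats[(i, tau, j)]
                links.append(CausalLink(i, j, tau, p_value=p, rho=rho))

    pairs = set()
    for j in range(n):
        for (i, tau) in skeleton.adjacency[j]:
            if tau == 0:
                pairs.add((min(i, j), max(i, j)))

    directed, conflict, _ = _orient_pairs(
        n, pairs, lambda a, b: _skeleton_sepset(skeleton, a, b)
    )

    def pair_stats(a: int, b: int) -> tuple[float, float]:
        return skeleton.stats.get((a, 0, b)) or skeleton.stats.get((b, 0, a))

    for pair in sorted(pairs):
        a, b = pair
        if pair in directed:
            src, snk = directed[pair]
            rho, p = skeleton.stats.get((src, 0, snk)) or pair_stats(a, b)
            links.append(CausalLink(src, snk, 0, p_value=p, rho=rho, orientation="directed"))
        else:
            rho, p = pair_stats(a, b)
            kind = "conflict" if pair in conflict else "unoriented"
            links.append(CausalLink(a, b, 0, p_value=p, rho=rho, orientation=kind))

    return CausalGraph(
        n_vars=n,
        tau_max=skeleton.tau_max,
        alpha=skeleton.alpha,
        links=links,
        names=skeleton.names,
    )


def _lagged_parents(graph: CausalGraph) -> dict[int, list[Var]]:
    parents: dict[int, list[Var]] = {j: [] for j in range(graph.n_vars)}
    for link in graph.links:
        if link.lag >= 1:
            parents[link.sink].append((link.source, link.lag))
    return {j: sorted(v) for j, v in parents.items()}


def mci_validate(
    panel: TimeSeriesPanel | np.ndarray,
    graph: CausalGraph,
    alpha: float,
    _tester: _Tester | None = None,
) -> CausalGraph:
    """Momentary-conditional-independence validation of every link.

    Link ``X_{t-tau}^i -> X_t^j`` is retained iff the ParCorr test given
    ``parents(X_t^j) \\ {(i, tau)}`` united with the tau-shifted lagged
    parents of ``X_{t-tau}^i`` yields ``p <= alpha``.
    """
    values, names = _as_values(panel)
    tester = _tester or _Tester(values, graph.tau_max)
    parents = _lagged_parents(graph)
    kept: list[CausalLink] = []
    for link in graph.links:
        i, j, tau = link.source, link.sink, link.lag
        cond = {p for p in parents[j] if p != (i, tau)}
        cond |= {(k, t + tau) for (k, t) in parents[i]}
        cond.discard((i, tau))
        cond.discard((j, 0))
        rho, p = tester.test((i, tau), (j, 0), sorted(cond))
        if p <= alpha:
            kept.append(
                CausalLink(i, j, tau, p_value=p, rho=rho, orientation=link.orientation)
            )
    return CausalGraph(
        n_vars=graph.n_vars,
        tau_max=graph.tau_max,
        alpha=alpha,
        links=kept,
        names=graph.names or names,
    )


def _reorient_contemporaneous(graph: CausalGraph, skeleton: Skeleton) -> CausalGraph:
    """Redo lag-0 orientation on the MCI-surviving adjacency.

    MCI can remove contemporaneous pairs the lax skeleton kept (e.g. pairs
    shielded only by conditioning on a common effect), changing which
    triples are unshielded.  A pair now absent was separated either by a
    recorded skeleton sepset or by an MCI conditioning set — the latter
    contains only lagged variables, so an empty-set fallback gives the
    collider rule the correct answer.
    """
    pairs = {
        (min(l.source, l.sink), max(l.source, l.sink))
        for l in graph.links
        if l.lag == 0
    }

    def sepset(a: int, b: int) -> list[Var]:
        return _skeleton_sepset(skeleton, a, b)

    directed, conflict, _ = _orient_pairs(graph.n_vars, pairs, sepset)
    links = [l for l in graph.links if l.lag >= 1]
    for link in graph.links:
        if link.lag != 0:
            continue
        pair = (min(link.source, link.sink), max(link.source, link.sink))
        if pair in directed:
            src, snk = directed[pair]
            kind = "directed"
        else:
            (src, snk), kind = pair, ("conflict" if pair in conflict else "unoriented")
        # rho and the MCI p-value are symmetric in the endpoints
        links.append(
            CausalLink(src, snk, 0, p_value=link.p_value, rho=link.rho, orientation=kind)
        )
    return CausalGraph(
        n_vars=graph.n_vars,
        tau_max=graph.tau_max,
        alpha=graph.alpha,
        links=links,
        names=graph.names,
    )


def run_pcmciplus(
    panel: TimeSeriesPanel | np.ndarray,
    tau_max: int = 7,
    alpha: float = 0.05,
    pc_alpha: float = 0.2,
) -> CausalGraph:
    """Full discovery: skeleton -> orientation -> MCI validation.

    The skeleton (condition-selection) phase runs at ``pc_alpha`` — a laxer
    level whose job is to find candidate parents, not to decide links; the
    MCI stage makes the level-``alpha`` decision (``pc_alpha`` is clipped
    up to ``alpha``).  Contemporaneous orientation is refreshed on the
    MCI-surviving adjacency, where shielding spuriously introduced by the
    lax skeleton has been cleared.
    """
    values, _ = _as_values(panel)
    tester = _Tester(values, tau_max)
    skeleton = discover_skeleton(panel, tau_max, max(alpha, pc_alpha), _tester=tester)
    graph = orient_links(skeleton)
    validated = mci_validate(panel, graph, alpha, _tester=tester)
    return _reorient_contemporaneous(validated, skeleton)
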