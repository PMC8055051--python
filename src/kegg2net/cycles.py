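"""Cycle removal: converting a gene network into a DAG.

Bayesian-network scoring needs acyclic graphs, but pathway-derived gene
networks routinely contain feedback loops.  Four alternative conversions are
provided:

``dfs``
    Depth-first search from every root in lexicographic order; back edges
    (edges onto the current traversal stack) are removed.
``mfas``
    The Eades–Lin–Smyth greedy sequence heuristic for the minimum feedback
    arc set: build a vertex sequence by peeling sinks to the right and
    sources to the left, otherwise moving the vertex with maximal
    out-degree − in-degree left; edges pointing right-to-left are removed.
``pr``
    A hierarchy inferred by PageRank; edges violating the score order are
    removed (both orientations of the hierarchy are tried, keeping the one
    that removes fewer edges).
``en``
    An ensemble of two hierarchies — TrueSkill skill ratings (each edge u→v
    treated as a match won by v) and a social-agony-minimising integer
    ranking.  Edges vote by how many hierarchies they violate; the
    worst-voted edge still lying on a cycle is removed until acyclic.

All methods share the hierarchy convention that scores increase along edge
direction, are deterministic (lexicographic tie-breaks, explicit seeds), and
return a :class:`DAGResult` partitioning the input edges into kept and
removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import ContractError, GeneNetwork

METHODS = ("dfs", "mfas", "pr", "en")


@dataclass
class NodeScores:
    """A hierarchy over genes: one finite score per gene.

    ``method`` is ``pagerank``/``trueskill`` (real scores) or ``agony``
    (nonnegative integer rank levels).
    """

    method: str
    score: dict[str, float]


@dataclass
class DAGResult:
    method: str  # dfs | mfas | pr | en
    dag: GeneNetwork
    removed_edges: list[tuple[str, str]]

    @property
    def n_removed(self) -> int:
        return len(self.removed_edges)


def _result(g: GeneNetwork, method: str, removed: list[tuple[str, str]]) -> DAGResult:
    removed_set = set(removed)
    kept = {e: s for e, s in g.edges.items() if e not in removed_set}
    return DAGResult(method=method, dag=GeneNetwork(list(g.genes), kept), removed_edges=list(removed))


def _successors(g: GeneNetwork) -> dict[str, list[str]]:
    succ: dict[str, list[str]] = {n: [] for n in g.genes}
    for u, v in g.edges:
        succ[u].append(v)
    for n in succ:
        succ[n].sort()
    return succ


def remove_cycles_dfs(g: GeneNetwork) -> DAGResult:
    """Remove DFS back edges.

    Roots are visited in lexicographic gene order, neighbours expand in
    lexicographic order; an edge onto a node currently on the DFS stack is a
    back edge and is removed.  Tree, forward and cross edges are kept, so an
    acyclic input loses nothing.
    """
    succ = _successors(g)
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {n: WHITE for n in g.genes}
    removed: list[tuple[str, str]] = []
    for root in sorted(g.genes):
        if color[root] != WHITE:
            continue
        color[root] = GRAY
        stack = [(root, iter(succ[root]))]
        while stack:
            node, it = stack[-1]
            nxt = next(it, None)
            if nxt is None:
                color[node] = BLACK
                stack.pop()
            elif color[nxt] == WHITE:
                color[nxt] = GRAY
                stack.append((nxt, iter(succ[nxt])))
            elif color[nxt] == GRAY:
                removed.append((node, nxt))
            # BLACK: forward/cross edge, kept
    return _result(g, "dfs", removed)


def remove_cycles_mfas(g: GeneNetwork) -> DAGResult:
    """Eades–Lin–Smyth greedy feedback-arc-set heuristic.

    Repeatedly: move any sink to the right end of the sequence, any source to
    the left end, otherwise the vertex maximising out-degree − in-degree to
    the left end (ties lexicographic).  Edges pointing right-to-left in the
    final sequence are the feedback set.
    """
    outs: dict[str, set[str]] = {n: set() for n in g.genes}
    ins: dict[str, set[str]] = {n: set() for n in g.genes}
    for u, v in g.edges:
        outs[u].add(v)
        ins[v].add(u)
    remaining = set(g.genes)
    left: list[str] = []
    right: list[str] = []  # built reversed; prepends append here

    def drop(n: str) -> None:
        remaining.discard(n)
        for v in outs[n]:
            ins[v].discard(n)
        for u in ins[n]:
            outs[u].discard(n)

    while remaining:
        sinks = sorted(n for n in remaining if not outs[n])
        if sinks:
            right.append(sinks[0])
            drop(sinks[0])
            continue
        sources = sorted(n for n in remaining if not ins[n])
        if sources:
            left.append(sources[0])
            drop(sources[0])
            continue
        pick = min(remaining, key=lambda n: (-(len(outs[n]) - len(ins[n])), n))
        left.append(pick)
        drop(pick)

    order = left + right[::-1]
    pos = {n: i for i, n in enumerate(order)}
    removed = sorted(e for e in g.edges if pos[e[0]] > pos[e[1]])
    return _result(g, "mfas", removed)


def pagerank_scores(g: GeneNetwork, damping: float = 0.85, tol: float = 1e-10, max_iter: int = 100_000) -> NodeScores:
    """PageRank by power iteration with uniform teleport.

    Dangling mass is redistributed uniformly; iteration stops when the
    maximum absolute score change falls below ``tol``.  Scores sum to 1.
    """
    if not g.genes:
        raise ContractError("pagerank_scores requires a non-empty network")
    genes = list(g.genes)
    idx = {n: i for i, n in enumerate(genes)}
    n = len(genes)
    outdeg = np.zeros(n)
    src, dst = [], []
    for u, v in g.edges:
        outdeg[idx[u]] += 1
        src.append(idx[u])
        dst.append(idx[v])
    src = np.asarray(src, dtype=int)
    dst = np.asarray(dst, dtype=int)
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        contrib = np.zeros(n)
        if len(src):
            np.add.at(contrib, dst, x[src] / outdeg[src])
        dangling = x[outdeg == 0].sum()
        x_new = (1.0 - damping) / n + damping * (contrib + dangling / n)
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    return NodeScores(method="pagerank", score={genes[i]: float(x[i]) for i in range(n)})


def remove_by_hierarchy(g: GeneNetwork, scores: NodeScores) -> DAGResult:
    """Remove every edge violating the ascending-score total order.

    Genes are totally ordered by (score, name); an edge from a later to an
    earlier position violates the hierarchy and is removed.  Any total order
    with no violating edge is acyclic, so the result is a DAG.
    """
    missing = [n for n in g.genes if n not in scores.score]
    if missing:
        raise ContractError(f"scores missing for genes: {missing[:5]}")
    order = sorted(g.genes, key=lambda n: (scores.score[n], n))
    pos = {n: i for i, n in enumerate(order)}
    removed = sorted(e for e in g.edges if pos[e[0]] > pos[e[1]])
    method = {"pagerank": "pr", "trueskill": "en", "agony": "en"}.get(scores.method, scores.method)
    return _result(g, method, removed)


def remove_cycles_pagerank(g: GeneNetwork, damping: float = 0.85, tol: float = 1e-10) -> DAGResult:
    """Hierarchy removal with a PageRank-inferred hierarchy.

    Whether high PageRank should sit at the top or the bottom of the
    hierarchy is ambiguous, so both orientations are evaluated and the one
    removing fewer edges wins (ties → ascending).  An input that is already
    acyclic is returned untouched — hierarchy violations in a DAG carry no
    cycle and need no repair.
    """
    if nx.is_directed_acyclic_graph(g.to_networkx()):
        return _result(g, "pr", [])
    scores = pagerank_scores(g, damping=damping, tol=tol)
    asc = remove_by_hierarchy(g, scores)
    desc = remove_by_hierarchy(g, NodeScores("pagerank", {n: -s for n, s in scores.score.items()}))
    best = asc if asc.n_removed <= desc.n_removed else desc
    return DAGResult(method="pr", dag=best.dag, removed_edges=best.removed_edges)


# --- TrueSkill -------------------------------------------------------------

_TS_MU0 = 25.0
_TS_SIGMA0 = 25.0 / 3.0
_TS_BETA = _TS_SIGMA0 / 2.0
_TS_TAU = _TS_SIGMA0 / 100.0
_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _norm_pdf(t: float) -> float:
    return math.exp(-0.5 * t * t) * _INV_SQRT_2PI


def _norm_cdf(t: float) -> float:
    return 0.5 * math.erfc(-t / _SQRT2)


def trueskill_scores(g: GeneNetwork, epochs: int = 10, seed: int = 0) -> NodeScores:
    """TrueSkill skill means with each edge u→v scored as a win for v.

    Standard two-player no-draw updates with the canonical priors
    (μ₀=25, σ₀=25/3, β=σ₀/2, τ=σ₀/100).  Edges are replayed for ``epochs``
    passes in an order shuffled by the seeded generator; the returned score
    is the final mean, so genes that win often (receive many edges) float up
    the hierarchy.
    """
    mu = {n: _TS_MU0 for n in g.genes}
    var = {n: _TS_SIGMA0**2 for n in g.genes}
    edges = sorted(g.edges)
    rng = np.random.default_rng(seed)
    for _ in range(epochs):
        for i in rng.permutation(len(edges)):
            loser, winner = edges[i]
            var[winner] += _TS_TAU**2
            var[loser] += _TS_TAU**2
            c2 = 2.0 * _TS_BETA**2 + var[winner] + var[loser]
            c = math.sqrt(c2)
            t = (mu[winner] - mu[loser]) / c
            cdf = max(_norm_cdf(t), 1e-300)
            v = _norm_pdf(t) / cdf
            w = v * (v + t)
            mu[winner] += var[winner] / c * v
            mu[loser] -= var[loser] / c * v
            var[winner] *= max(1.0 - var[winner] / c2 * w, 1e-12)
            var[loser] *= max(1.0 - var[loser] / c2 * w, 1e-12)
    return NodeScores(method="trueskill", score=dict(mu))


# --- social agony ----------------------------------------------------------


def agony_of_ranking(g: GeneNetwork, ranks: NodeScores) -> int:
    """Σ over edges u→v of max(0, rank(u) − rank(v) + 1).

    A zero-agony ranking orders every edge strictly upward; agony counts how
    far (in rank levels) each edge violates the hierarchy.
    """
    total = 0
    for u, v in g.edges:
        ru, rv = ranks.score[u], ranks.score[v]
        for r in (ru, rv):
            if r != int(r) or r < 0:
                raise ContractError(f"agony requires nonnegative integer ranks, got {r!r}")
        total += max(0, int(ru) - int(rv) + 1)
    return total


def _longest_path_levels(dag: GeneNetwork) -> dict[str, int]:
    order = list(nx.topological_sort(dag.to_networkx()))
    level = {n: 0 for n in dag.genes}
    preds: dict[str, list[str]] = {n: [] for n in dag.genes}
    for u, v in dag.edges:
        preds[v].append(u)
    for n in order:
        if preds[n]:
            level[n] = max(level[p] + 1 for p in preds[n])
    return level


def _agony_local_search(g: GeneNetwork, ranks: dict[str, int], n_levels: int, max_sweeps: int) -> dict[str, int]:
    """Single-node moves: re-assign each gene the rank minimising its incident agony."""
    outs: dict[str, list[str]] = {n: [] for n in g.genes}
    ins: dict[str, list[str]] = {n: [] for n in g.genes}
    for u, v in g.edges:
        outs[u].append(v)
        ins[v].append(u)

    def incident(node: str, r: int) -> int:
        a = sum(max(0, r - ranks[v] + 1) for v in outs[node])
        a += sum(max(0, ranks[u] - r + 1) for u in ins[node])
        return a

    nodes = sorted(g.genes)
    for _ in range(max_sweeps):
        improved = False
        for node in nodes:
            cur = incident(node, ranks[node])
            best_r, best_a = ranks[node], cur
            for r in range(n_levels):
                a = incident(node, r)
                if a < best_a or (a == best_a and r < best_r):
                    best_r, best_a = r, a
            if best_a < cur:
                ranks[node] = best_r
                improved = True
        if not improved:
            break
    return ranks


def min_agony_ranking(g: GeneNetwork, max_sweeps: int = 100, n_restarts: int = 5) -> NodeScores:
    """Heuristically agony-minimising integer rank levels.

    Deterministic multi-start local search: single-node rank moves (each
    gene to the level minimising its incident agony, sweeping until no move
    improves or ``max_sweeps``) from several starts — longest-path levels of
    the DFS-debacked DAG (already agony 0 on acyclic inputs), the all-equal
    ranking, sink-depth levels, and ``n_restarts`` fixed-seed random rank
    vectors.  The lowest-agony result wins.  Plain single-start descent
    stalls on plateaus of dense cyclic graphs; the extra starts are what
    keep the heuristic near the exact optimum at small sizes.
    """
    if not g.genes:
        return NodeScores(method="agony", score={})
    n_levels = len(g.genes)
    dag = remove_cycles_dfs(g).dag
    levels = _longest_path_levels(dag)
    reversed_dag = GeneNetwork(list(dag.genes), {(v, u): s for (u, v), s in dag.edges.items()})
    depth = _longest_path_levels(reversed_dag)
    max_depth = max(depth.values(), default=0)
    starts = [
        dict(levels),
        {n: 0 for n in g.genes},
        {n: max_depth - depth[n] for n in g.genes},
    ]
    rng = np.random.default_rng(20210305)  # fixed: the heuristic itself is seedless
    ordered = sorted(g.genes)
    for _ in range(n_restarts):
        starts.append({n: int(r) for n, r in zip(ordered, rng.integers(0, n_levels, size=len(ordered)))})

    best_ranks, best_agony = None, None
    for start in starts:
        ranks = _agony_local_search(g, dict(start), n_levels, max_sweeps)
        agony = sum(max(0, ranks[u] - ranks[v] + 1) for u, v in g.edges)
        if best_agony is None or agony < best_agony:
            best_ranks, best_agony = ranks, agony
    base = min(best_ranks.values())
    return NodeScores(method="agony", score={n: r - base for n, r in best_ranks.items()})


def remove_cycles_ensemble(g: GeneNetwork, seed: int = 0) -> DAGResult:
    """Ensemble removal from TrueSkill and agony hierarchies.

    Each edge u→v gets one vote per hierarchy it violates (score(u) ≥
    score(v)) and a violation magnitude Σ score(u) − score(v) over the voting
    hierarchies.  While cycles remain, the edge lying on a cycle with
    (most votes, largest magnitude, lexicographic) is removed; re-checking
    cycle membership after every removal keeps the removal set lean.
    """
    ts = trueskill_scores(g, epochs=10, seed=seed)
    ag = min_agony_ranking(g)
    votes: dict[tuple[str, str], int] = {}
    mag: dict[tuple[str, str], float] = {}
    for e in g.edges:
        u, v = e
        votes[e] = 0
        mag[e] = 0.0
        if ts.score[u] >= ts.score[v]:
            votes[e] += 1
            mag[e] += ts.score[u] - ts.score[v]
        if ag.score[u] >= ag.score[v]:
            votes[e] += 1
            mag[e] += ag.score[u] - ag.score[v]

    work = nx.DiGraph()
    work.add_nodes_from(g.genes)
    work.add_edges_from(g.edges)
    removed: list[tuple[str, str]] = []
    while True:
        cycle_edges = set()
        for scc in nx.strongly_connected_components(work):
            if len(scc) > 1:
                cycle_edges.update((u, v) for u, v in work.edges() if u in scc and v in scc)
        if not cycle_edges:
            break
        target = min(cycle_edges, key=lambda e: (-votes[e], -mag[e], e))
        work.remove_edge(*target)
        removed.append(target)
    return _result(g, "en", removed)


def convert(g: GeneNetwork, method: str, seed: int = 0) -> DAGResult:
    """Dispatch to one of the four conversion methods by tag."""
    if method == "dfs":
        return remove_cycles_dfs(g)
    if method == "mfas":
        return remove_cycles_mfas(g)
    if method == "pr":
        return remove_cycles_pagerank(g)
    if method == "en":
        return remove_cycles_ensemble(g, seed=seed)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
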