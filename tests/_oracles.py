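"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (path
enumeration, permutation search, exhaustive rank vectors, dict-based
counting) and never call the implementation paths they check.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import networkx as nx
import numpy as np

from kegg2net.kgml import HeteroGraph
from kegg2net.network import ACTIVATING, INHIBITING, UNKNOWN


def collapse_oracle(h: HeteroGraph) -> dict[tuple[str, str], str]:
    """All-simple-paths collapse: edge g1→g2 iff a path with all-non-gene
    internal nodes exists; sign by product over each such path."""
    genes = sorted(n for n, k in h.kinds.items() if k == "gene")
    nongenes = [n for n, k in h.kinds.items() if k != "gene"]
    full = nx.DiGraph()
    full.add_nodes_from(h.kinds)
    for (u, v), sign in h.edges.items():
        full.add_edge(u, v, sign=sign)
    result: dict[tuple[str, str], str] = {}
    for g1 in genes:
        for g2 in genes:
            if g1 == g2:
                continue
            sub = full.subgraph([g1, g2, *nongenes])
            if not (sub.has_node(g1) and sub.has_node(g2)):
                continue
            signs = set()
            for path in nx.all_simple_paths(sub, g1, g2):
                s = ACTIVATING
                for a, b in zip(path, path[1:]):
                    t = sub.edges[a, b]["sign"]
                    s = UNKNOWN if (s == UNKNOWN or t == UNKNOWN) else (ACTIVATING if s == t else INHIBITING)
                signs.add(s)
            if signs:
                result[(g1, g2)] = signs.pop() if len(signs) == 1 else UNKNOWN
    return result


def mfas_optimum(genes, edges) -> int:
    """Minimum feedback arc set size by permutation search (small n only)."""
    best = len(edges)
    for perm in itertools.permutations(genes):
        pos = {n: i for i, n in enumerate(perm)}
        best = min(best, sum(1 for u, v in edges if pos[u] > pos[v]))
        if best == 0:
            break
    return best


def agony_optimum(genes, edges) -> int:
    """Exhaustive minimum agony over rank vectors in {0..n-1}^n (small n only)."""
    n = len(genes)
    best = None
    for ranks in itertools.product(range(n), repeat=n):
        r = dict(zip(genes, ranks))
        a = sum(max(0, r[u] - r[v] + 1) for u, v in edges)
        best = a if best is None else min(best, a)
        if best == 0:
            break
    return best


def local_bic_oracle(target: str, parents, frame) -> float:
    """Dict-and-Counter reimplementation of the local multinomial BIC."""
    y = list(frame.loc[target])
    n = len(y)
    parents = sorted(parents)
    if parents:
        cfgs = [tuple(frame.loc[p][i] for p in parents) for i in range(n)]
    else:
        cfgs = [()] * n
    joint = Counter(zip(cfgs, y))
    marg = Counter(cfgs)
    ll = sum(c * math.log(c / marg[cfg]) for (cfg, _), c in joint.items())
    r = len(set(y))
    q = len(marg)
    return ll - math.log(n) / 2.0 * q * (r - 1)


def random_hetero_graph(seed: int, max_nodes: int = 12) -> HeteroGraph:
    """Random small heterogeneous graph with mixed node kinds and signs."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_nodes + 1))
    kinds = {}
    for i in range(n):
        kind = ["gene", "gene", "compound", "map", "other"][int(rng.integers(5))]
        name = f"{kind[0]}{i:02d}"
        kinds[name] = kind
    nodes = sorted(kinds)
    m = int(rng.integers(0, min(2 * n, n * (n - 1)) + 1))
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    edges = {}
    for c in rng.choice(len(pairs), size=min(m, len(pairs)), replace=False):
        sign = [ACTIVATING, INHIBITING, UNKNOWN][int(rng.integers(3))]
        edges[pairs[int(c)]] = sign
    return HeteroGraph(kinds=kinds, edges=edges)


def all_digraphs(nodes):
    """Every labelled digraph (no self-loops) on the given nodes."""
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    for mask in range(1 << len(pairs)):
        yield {pairs[i] for i in range(len(pairs)) if mask >> i & 1}
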