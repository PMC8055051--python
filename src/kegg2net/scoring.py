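"""Multinomial Bayesian-network BIC scoring and the random-DAG null.

A DAG is scored against discretized expression data with the decomposable
BIC (bnlearn sign convention: higher is better, natural log):

    BIC(G) = Σ_v [ Σ_{j,k} N_jk · ln(N_jk / N_j)  −  (ln N)/2 · q_v · (r_v − 1) ]

where, per gene v, r_v is the number of observed target states, q_v the
number of observed parent configurations (1 when parentless), and N_jk the
count of samples with parent configuration j and target state k.  States and
configurations are counted from the data, not a declared alphabet.

The null model matches the design of comparing each DAG against random DAGs
with identical node and edge counts: :func:`sample_random_dag` draws a
uniform permutation and then edges uniformly among its forward pairs.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd

from .network import UNKNOWN, ContractError, GeneNetwork


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    # ExpressionDataset with a discrete matrix
    if getattr(data, "discrete", None) is not None:
        return pd.DataFrame(data.discrete, index=data.genes)
    raise ContractError("data must be a DataFrame of discrete levels or a discretized ExpressionDataset")


def local_bic(target: str, parents, data, N: int | None = None) -> float:
    """BIC contribution of one gene given its parent set."""
    frame = _as_frame(data)
    parents = sorted(parents)
    if target in parents:
        raise ContractError(f"target {target!r} cannot be its own parent")
    y = frame.loc[target].to_numpy()
    n = N if N is not None else y.shape[0]
    _, y_idx = np.unique(y, return_inverse=True)
    r = int(y_idx.max()) + 1
    if parents:
        pmat = frame.loc[parents].to_numpy()
        _, cfg = np.unique(pmat.T, axis=0, return_inverse=True)
        q = int(cfg.max()) + 1
    else:
        cfg = np.zeros_like(y_idx)
        q = 1
    counts = np.bincount(cfg * r + y_idx, minlength=q * r).reshape(q, r).astype(float)
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(counts / row_tot), 0.0).sum()
    penalty = math.log(n) / 2.0 * q * (r - 1)
    return float(ll - penalty)


def bic_score(dag: GeneNetwork, data) -> float:
    """Decomposable BIC of a DAG: sum of local scores over its genes."""
    nxg = dag.to_networkx()
    if not nx.is_directed_acyclic_graph(nxg):
        cyc = nx.find_cycle(nxg)
        raise ContractError(f"graph is cyclic, e.g. {' -> '.join(u for u, _ in cyc)} -> {cyc[0][0]}")
    frame = _as_frame(data)
    missing = [g for g in dag.genes if g not in frame.index]
    if missing:
        raise ContractError(f"genes absent from data: {missing[:5]}")
    parents: dict[str, list[str]] = {g: [] for g in dag.genes}
    for u, v in dag.edges:
        parents[v].append(u)
    n = frame.shape[1]
    return sum(local_bic(g, parents[g], frame, N=n) for g in dag.genes)


def sample_random_dag(genes, n_edges: int, seed: int) -> GeneNetwork:
    """Random DAG with the given genes and exactly ``n_edges`` edges.

    Draws a uniform permutation of the genes, then ``n_edges`` distinct
    ordered pairs uniformly among the forward pairs of that permutation.
    """
    genes = list(genes)
    n = len(genes)
    max_edges = n * (n - 1) // 2
    if n_edges > max_edges:
        raise ContractError(f"n_edges={n_edges} exceeds max acyclic {max_edges} for {n} genes")
    rng = np.random.default_rng(seed)
    perm = [genes[i] for i in rng.permutation(n)]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    chosen = rng.choice(max_edges, size=n_edges, replace=False) if n_edges else []
    edges = {(perm[pairs[c][0]], perm[pairs[c][1]]): UNKNOWN for c in chosen}
    return GeneNetwork(genes=genes, edges=edges)


def rank_scores(method_scores: dict[str, float]) -> dict[str, int]:
    """Dense descending rank over the four methods; ties share the better rank."""
    uniq = sorted(set(method_scores.values()), reverse=True)
    rank_of = {s: i + 1 for i, s in enumerate(uniq)}
    return {m: rank_of[s] for m, s in method_scores.items()}


def rank_against_randoms(score: float, random_scores) -> int:
    """How many random-DAG scores strictly beat the method's score."""
    return int(sum(1 for s in random_scores if s > score))
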