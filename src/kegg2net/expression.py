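"""Synthetic steady-state gene expression consistent with a network topology.

The simulator emulates the SynTReN class of generators: each edge carries a
Hill transfer function (activator ``x^n/(K^n + x^n)`` or repressor
``K^n/(K^n + x^n)``), regulator-free genes act as external conditions drawn
uniformly per sample, and regulated genes relax to a steady state of

    x_v = b_v + (1 - b_v) * mean_e h_e(x_u)        (clipped to [0, 1])

under damped synchronous fixed-point iteration — cyclic networks are solved
the same way, with a convergence flag.  Gaussian measurement noise is added
and values are clipped to [0, 1].  A quantile (equal-frequency) discretizer
prepares the data for multinomial Bayesian-network scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import ACTIVATING, INHIBITING, ContractError, GeneNetwork

ACTIVATOR = "activator"
REPRESSOR = "repressor"


@dataclass
class EdgeKinetics:
    hill_n: int  # Hill coefficient, 1..10
    half_saturation: float  # K, in [0.05, 1.0]
    role: str  # activator | repressor

    def transfer(self, x: float) -> float:
        xn = x**self.hill_n
        kn = self.half_saturation**self.hill_n
        return xn / (kn + xn) if self.role == ACTIVATOR else kn / (kn + xn)


@dataclass
class KineticModel:
    network: GeneNetwork
    edge_params: dict[tuple[str, str], EdgeKinetics]
    basal: dict[str, float]  # per-gene basal level b, in [0.01, 0.2]


@dataclass
class ExpressionDataset:
    genes: list[str]
    continuous: np.ndarray  # genes x samples, values in [0, 1]
    discrete: np.ndarray | None = None  # genes x samples, levels 0..L-1
    converged: list[bool] = field(default_factory=list)  # per sample

    @property
    def n_samples(self) -> int:
        return self.continuous.shape[1]

    def to_frame(self, which: str = "continuous") -> pd.DataFrame:
        mat = self.continuous if which == "continuous" else self.discrete
        if mat is None:
            raise ValueError(f"{which} matrix not present")
        return pd.DataFrame(mat, index=self.genes, columns=[f"s{i}" for i in range(mat.shape[1])])


def assign_kinetics(g: GeneNetwork, seed: int) -> KineticModel:
    """Sample Hill parameters per edge and a basal level per gene.

    Signed edges keep their role (activating→activator, inhibiting→
    repressor); unsigned edges are assigned a role uniformly.  Deterministic
    given (network, seed).
    """
    rng = np.random.default_rng(seed)
    params: dict[tuple[str, str], EdgeKinetics] = {}
    for e in sorted(g.edges):
        sign = g.edges[e]
        n = int(rng.integers(1, 11))
        k = float(rng.uniform(0.05, 1.0))
        if sign == ACTIVATING:
            role = ACTIVATOR
        elif sign == INHIBITING:
            role = REPRESSOR
        else:
            role = ACTIVATOR if rng.random() < 0.5 else REPRESSOR
        params[e] = EdgeKinetics(n, k, role)
    basal = {gene: float(rng.uniform(0.01, 0.2)) for gene in sorted(g.genes)}
    return KineticModel(network=g, edge_params=params, basal=basal)


def root_genes(g: GeneNetwork) -> list[str]:
    """Regulator-free genes (in-degree 0), sorted."""
    regulated = {v for _, v in g.edges}
    return sorted(set(g.genes) - regulated)


def steady_state(
    m: KineticModel,
    inputs: dict[str, float],
    alpha: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[dict[str, float], bool]:
    """Damped fixed-point solve of the regulatory update rule.

    ``inputs`` must cover exactly the regulator-free genes, which are held
    fixed; every regulated gene starts at 0.5 and is updated as
    x ← (1−α)·x + α·f(x) until the largest change drops below ``tol``.
    Returns the levels and a convergence flag.
    """
    roots = root_genes(m.network)
    if set(inputs) != set(roots):
        raise ContractError(f"inputs must cover exactly the regulator-free genes {roots}, got {sorted(inputs)}")
    incoming: dict[str, list[tuple[str, EdgeKinetics]]] = {g: [] for g in m.network.genes}
    for (u, v), kin in m.edge_params.items():
        incoming[v].append((u, kin))
    x = {g: (inputs[g] if g in inputs else 0.5) for g in m.network.genes}
    regulated = [g for g in m.network.genes if incoming[g]]
    converged = False
    for _ in range(max_iter):
        delta = 0.0
        new = {}
        for v in regulated:
            b = m.basal[v]
            drive = sum(kin.transfer(x[u]) for u, kin in incoming[v]) / len(incoming[v])
            fv = min(1.0, max(0.0, b + (1.0 - b) * drive))
            new[v] = (1.0 - alpha) * x[v] + alpha * fv
        for v, val in new.items():
            delta = max(delta, abs(val - x[v]))
            x[v] = val
        if delta < tol:
            converged = True
            break
    return x, converged


def generate_expression(
    m: KineticModel,
    n_samples: int,
    noise_sd: float = 0.05,
    seed: int = 0,
    alpha: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> ExpressionDataset:
    """Simulate an expression matrix (genes × samples).

    Per sample, regulator-free genes get independent uniform(0,1) external
    conditions, the steady state is solved, Gaussian noise (sd ``noise_sd``)
    is added, and values are clipped to [0, 1].
    """
    if n_samples < 1:
        raise ContractError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    genes = list(m.network.genes)
    roots = root_genes(m.network)
    mat = np.zeros((len(genes), n_samples))
    flags: list[bool] = []
    for j in range(n_samples):
        inputs = {r: float(rng.uniform()) for r in roots}
        levels, ok = steady_state(m, inputs, alpha=alpha, tol=tol, max_iter=max_iter)
        mat[:, j] = [levels[g] for g in genes]
        flags.append(ok)
    if noise_sd > 0:
        mat = mat + rng.normal(0.0, noise_sd, size=mat.shape)
    mat = np.clip(mat, 0.0, 1.0)
    return ExpressionDataset(genes=genes, continuous=mat, converged=flags)


def discretize(d: ExpressionDataset, levels: int = 3) -> ExpressionDataset:
    """Equal-frequency (quantile) discretization, per gene.

    Cutpoints are the k/levels quantiles of the gene's row; a value lands in
    the number of cutpoints strictly below it, so boundary ties go to the
    lower bin and a constant row maps to all zeros.
    """
    if levels < 2:
        raise ContractError("levels must be >= 2")
    if levels > d.n_samples:
        raise ContractError(f"levels ({levels}) exceeds sample count ({d.n_samples})")
    disc = np.zeros_like(d.continuous, dtype=np.int64)
    qs = [k / levels for k in range(1, levels)]
    for i in range(d.continuous.shape[0]):
        row = d.continuous[i]
        cuts = np.quantile(row, qs)
        disc[i] = sum((row > c).astype(np.int64) for c in cuts)
    return ExpressionDataset(genes=list(d.genes), continuous=d.continuous, discrete=disc, converged=list(d.converged))
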