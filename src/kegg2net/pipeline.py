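"""End-to-end workflow over a directory of KGML files.

Per pathway: parse KGML → heterogeneous graph → gene-only network → (if the
network has at least ``min_nonisolated`` non-isolated genes) four DAG
conversions; if the network is cyclic, synthetic expression data is
generated from the network topology, discretized, and each method's DAG is
BIC-scored against it alongside ``n_random_dags`` random DAGs matched to
that DAG's node and edge counts.  The per-pathway rows mirror the benchmark
table layout: counts, per-method edges removed and removal ranks, BIC
scores, within-method score ranks and random-DAG beat counts.

All randomness flows from one run seed through stable per-(pathway, stage)
derived seeds, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .cycles import METHODS, convert
from .expression import assign_kinetics, discretize, generate_expression
from .kgml import build_hetero_graph, parse_kgml
from .network import GeneNetwork, collapse_to_gene_network, has_cycle, nonisolated_count, serialize_network
from .scoring import bic_score, rank_against_randoms, rank_scores, sample_random_dag

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    methods: tuple[str, ...] = METHODS
    seed: int = 0
    n_samples: int = 100
    n_random_dags: int = 1000
    min_nonisolated: int = 6
    noise_sd: float = 0.05
    levels: int = 3
    formats: tuple[str, ...] = ("sif", "adjacency")
    orthologs_as_genes: bool = False
    do_scoring: bool = True  # False: convert only (no expression / BIC)

    def derived_seed(self, *tags) -> int:
        """Stable sub-seed below 2**31 from the run seed and string tags."""
        h = zlib.crc32(("|".join(str(t) for t in tags)).encode("utf-8"))
        return (self.seed * 1_000_003 + h) % (2**31 - 1)


@dataclass
class BenchmarkRecord:
    pathway_id: str
    pathway_name: str
    status: str = "ok"  # ok | skipped | failed
    n_nodes: int = 0
    n_edges: int = 0
    n_nonisolated: int = 0
    cyclic: bool = False
    edges_removed: dict[str, int] = field(default_factory=dict)
    removal_rank: dict[str, int] = field(default_factory=dict)
    score: dict[str, float] = field(default_factory=dict)
    score_rank: dict[str, int] = field(default_factory=dict)
    randoms_beating: dict[str, int] = field(default_factory=dict)
    n_random_dags: int = 0

    def to_row(self, methods) -> list[str]:
        row = [
            self.pathway_id,
            self.pathway_name,
            self.status,
            str(self.n_nodes),
            str(self.n_edges),
            str(self.n_nonisolated),
            str(int(self.cyclic)),
        ]
        for m in methods:
            row.append(str(self.edges_removed.get(m, "")))
        for m in methods:
            row.append(str(self.removal_rank.get(m, "")))
        for m in methods:
            s = self.score.get(m)
            row.append("" if s is None else f"{s:.6f}")
        for m in methods:
            row.append(str(self.score_rank.get(m, "")))
        for m in methods:
            row.append(str(self.randoms_beating.get(m, "")))
        row.append(str(self.n_random_dags or ""))
        return row


def record_header(methods) -> list[str]:
    cols = ["pathway_id", "pathway_name", "status", "n_nodes", "n_edges", "n_nonisolated", "cyclic"]
    cols += [f"edges_removed_{m}" for m in methods]
    cols += [f"removal_rank_{m}" for m in methods]
    cols += [f"bic_{m}" for m in methods]
    cols += [f"score_rank_{m}" for m in methods]
    cols += [f"randoms_beating_{m}" for m in methods]
    cols.append("n_random_dags")
    return cols


def dense_ascending_rank(values: dict[str, int]) -> dict[str, int]:
    uniq = sorted(set(values.values()))
    rank_of = {v: i + 1 for i, v in enumerate(uniq)}
    return {k: rank_of[v] for k, v in values.items()}


def _write_network_files(out_dir: Path, stem: str, net: GeneNetwork, formats) -> None:
    ext = {"sif": ".sif", "adjacency": ".adj.tsv"}
    for fmt in formats:
        (out_dir / f"{stem}{ext[fmt]}").write_text(serialize_network(net, fmt), encoding="utf-8")


def run_pathway(kgml_path, out_dir, config: RunConfig) -> BenchmarkRecord:
    """Process one KGML file; write network/DAG/expression/score artifacts."""
    kgml_path = Path(kgml_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = parse_kgml(kgml_path.read_text(encoding="utf-8"))
    net = collapse_to_gene_network(build_hetero_graph(model, orthologs_as_genes=config.orthologs_as_genes))
    stem = kgml_path.stem
    rec = BenchmarkRecord(
        pathway_id=model.pathway_id,
        pathway_name=model.title,
        n_nodes=len(net.genes),
        n_edges=net.n_edges,
        n_nonisolated=nonisolated_count(net),
    )
    _write_network_files(out_dir, f"{stem}.network", net, config.formats)
    if rec.n_nonisolated < config.min_nonisolated:
        rec.status = "skipped"
        return rec
    rec.cyclic = has_cycle(net)

    results = {}
    sidecar = ["source\ttarget\tmethod"]
    for m in config.methods:
        res = convert(net, m, seed=config.derived_seed(stem, m, "convert"))
        results[m] = res
        rec.edges_removed[m] = res.n_removed
        _write_network_files(out_dir, f"{stem}.dag.{m}", res.dag, config.formats)
        for u, v in res.removed_edges:
            sidecar.append(f"{u}\t{v}\t{m}")
    (out_dir / f"{stem}.removed_edges.tsv").write_text("\n".join(sidecar) + "\n", encoding="utf-8")
    rec.removal_rank = dense_ascending_rank(rec.edges_removed)

    if rec.cyclic and config.do_scoring:
        kin = assign_kinetics(net, seed=config.derived_seed(stem, "kinetics"))
        data = generate_expression(
            kin, n_samples=config.n_samples, noise_sd=config.noise_sd, seed=config.derived_seed(stem, "expression")
        )
        if sum(not ok for ok in data.converged) > 0.5 * len(data.converged):
            logger.warning("%s: over half of the samples did not converge", stem)
        data = discretize(data, levels=config.levels)
        _write_expression(out_dir, stem, data)
        rec.n_random_dags = config.n_random_dags
        for m in config.methods:
            dag = results[m].dag
            rec.score[m] = bic_score(dag, data)
            rand_scores = []
            for i in range(config.n_random_dags):
                rd = sample_random_dag(dag.genes, dag.n_edges, seed=config.derived_seed(stem, m, "random", i))
                rand_scores.append(bic_score(rd, data))
            rec.randoms_beating[m] = rank_against_randoms(rec.score[m], rand_scores)
            lines = [f"score\t{rec.score[m]:.6f}"] + [f"random\t{s:.6f}" for s in rand_scores]
            (out_dir / f"{stem}.scores.{m}.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
        rec.score_rank = rank_scores({m: rec.score[m] for m in config.methods})
    return rec


def _write_expression(out_dir: Path, stem: str, data) -> None:
    cols = "\t".join(f"s{i}" for i in range(data.n_samples))
    for suffix, mat, fmt in (("expr.tsv", data.continuous, "{:.6f}"), ("expr.disc.tsv", data.discrete, "{:d}")):
        lines = ["gene\t" + cols]
        for i, g in enumerate(data.genes):
            lines.append(g + "\t" + "\t".join(fmt.format(x) for x in mat[i]))
        (out_dir / f"{stem}.{suffix}").write_text("\n".join(lines) + "\n", encoding="utf-8")


def summarize(records: list[BenchmarkRecord], methods) -> dict[str, dict[str, float]]:
    """Per-method means over scored (cyclic) rows, plus removal means over converted rows."""
    converted = [r for r in records if r.status == "ok" and r.edges_removed]
    scored = [r for r in records if r.status == "ok" and r.score]
    out: dict[str, dict[str, float]] = {}
    for m in methods:
        entry: dict[str, float] = {}
        if converted:
            entry["mean_edges_removed"] = sum(r.edges_removed[m] for r in converted) / len(converted)
            entry["mean_removal_rank"] = sum(r.removal_rank[m] for r in converted) / len(converted)
        if scored:
            entry["mean_score_rank"] = sum(r.score_rank[m] for r in scored) / len(scored)
            entry["mean_randoms_beating"] = sum(r.randoms_beating[m] for r in scored) / len(scored)
        out[m] = entry
    return out


def run_benchmark(kgml_dir, out_dir, config: RunConfig) -> list[BenchmarkRecord]:
    """Run every KGML file in a directory; write the benchmark table, summary and manifest."""
    kgml_dir = Path(kgml_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = sorted(p for p in kgml_dir.iterdir() if p.suffix.lower() in {".xml", ".kgml"})
    if not files:
        raise FileNotFoundError(f"no KGML files (*.xml, *.kgml) in {kgml_dir}")
    records: list[BenchmarkRecord] = []
    for path in files:
        try:
            records.append(run_pathway(path, out_dir / path.stem, config))
        except Exception as exc:  # keep going; failures become rows
            logger.error("pathway %s failed: %s", path.name, exc)
            records.append(BenchmarkRecord(pathway_id=path.stem, pathway_name="", status="failed"))

    methods = config.methods
    lines = ["\t".join(record_header(methods))]
    for rec in records:
        lines.append("\t".join(rec.to_row(methods)))
    (out_dir / "benchmark.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    summary = summarize(records, methods)
    slines = ["method\tmean_edges_removed\tmean_removal_rank\tmean_score_rank\tmean_randoms_beating"]
    for m in methods:
        e = summary[m]
        slines.append(
            "\t".join(
                [m]
                + [("" if e.get(k) is None else f"{e[k]:.4f}") for k in
                   ("mean_edges_removed", "mean_removal_rank", "mean_score_rank", "mean_randoms_beating")]
            )
        )
    (out_dir / "summary.tsv").write_text("\n".join(slines) + "\n", encoding="utf-8")

    manifest = [
        f"kegg2net_version={__version__}",
        f"seed={config.seed}",
        f"methods={','.join(methods)}",
        f"n_samples={config.n_samples}",
        f"n_random_dags={config.n_random_dags}",
        f"min_nonisolated={config.min_nonisolated}",
        f"noise_sd={config.noise_sd}",
        f"levels={config.levels}",
        f"formats={','.join(config.formats)}",
        f"orthologs_as_genes={config.orthologs_as_genes}",
        f"n_pathways={len(records)}",
    ]
    (out_dir / "manifest.txt").write_text("\n".join(manifest) + "\n", encoding="utf-8")
    return records
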