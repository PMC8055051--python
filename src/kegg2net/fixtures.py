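"""Synthetic KGML documents and random gene networks.

The whole pipeline must be testable without downloading anything from KEGG,
so this module emits syntactically valid KGML from a compact
:class:`KGMLScenario` description (entries of every kind, relations with
subtypes, reversible reactions) and can randomise scenarios under a seed.
The scenario also knows the entry/link inventory its document should parse
to, which round-trip tests compare against the parser's output.

:func:`random_gene_network` provides seeded random directed networks (used
throughout the cycle-removal and scoring tests), with an option to guarantee
at least one directed cycle.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import UNKNOWN, GeneNetwork

_UNDIRECTED = {"binding/association", "dissociation"}
_COMPOUND_SUB = {"compound", "hidden compound"}


@dataclass
class EntrySpec:
    entry_id: str
    kind: str  # gene | ortholog | compound | map | group | enzyme
    names: list[str] = field(default_factory=list)
    members: list[str] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)


@dataclass
class RelationSpec:
    entry1: str
    entry2: str
    subtypes: list[tuple[str, str]] = field(default_factory=list)  # (name, value)


@dataclass
class ReactionSpec:
    rid: str
    name: str
    reversible: bool
    substrates: list[str] = field(default_factory=list)  # entry ids
    products: list[str] = field(default_factory=list)


@dataclass
class KGMLScenario:
    pathway_id: str
    title: str
    entries: list[EntrySpec] = field(default_factory=list)
    relations: list[RelationSpec] = field(default_factory=list)
    reactions: list[ReactionSpec] = field(default_factory=list)

    def expected_entry_count(self) -> int:
        return len(self.entries)

    def expected_link_count(self) -> int:
        """Links the parser should produce, by the same relation semantics."""
        total = 0
        for rel in self.relations:
            if not rel.subtypes:
                total += 1
                continue
            for name, _ in rel.subtypes:
                total += 2 if (name in _UNDIRECTED or name in _COMPOUND_SUB) else 1
        enzymes = {r: [] for r in [rx.name for rx in self.reactions]}
        for e in self.entries:
            for rname in e.reactions:
                if rname in enzymes:
                    enzymes[rname].append(e.entry_id)
        for rx in self.reactions:
            per_enzyme = (len(rx.substrates) + len(rx.products)) * (2 if rx.reversible else 1)
            total += per_enzyme * len(enzymes.get(rx.name, []))
        return total


def scenario_to_kgml(sc: KGMLScenario) -> str:
    """Serialise a scenario as a KGML document string."""
    root = ET.Element(
        "pathway",
        name=sc.pathway_id,
        org=sc.pathway_id.split(":")[-1][:3] if ":" in sc.pathway_id else "syn",
        number=sc.pathway_id[-5:] if len(sc.pathway_id) >= 5 else "00000",
        title=sc.title,
    )
    for e in sc.entries:
        el = ET.SubElement(root, "entry", id=e.entry_id, name=" ".join(e.names), type=e.kind)
        if e.reactions:
            el.set("reaction", " ".join(e.reactions))
        for m in e.members:
            ET.SubElement(el, "component", id=m)
        ET.SubElement(el, "graphics", name=(e.names[0] if e.names else e.entry_id), type="rectangle")
    for r in sc.relations:
        rel = ET.SubElement(root, "relation", entry1=r.entry1, entry2=r.entry2, type="PPrel")
        for name, value in r.subtypes:
            ET.SubElement(rel, "subtype", name=name, value=value)
    for rx in sc.reactions:
        el = ET.SubElement(root, "reaction", id=rx.rid, name=rx.name, type="reversible" if rx.reversible else "irreversible")
        for s in rx.substrates:
            ET.SubElement(el, "substrate", id=s, name=f"cpd:{s}")
        for p in rx.products:
            ET.SubElement(el, "product", id=p, name=f"cpd:{p}")
    ET.indent(root)
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(root, encoding="unicode") + "\n"


def random_scenario(
    seed: int,
    n_genes: int = 8,
    n_compounds: int = 3,
    n_maps: int = 1,
    n_groups: int = 1,
    n_relations: int = 14,
    n_reactions: int = 1,
    cycle: bool = True,
    multi_name_fraction: float = 0.2,
    pathway_number: int | None = None,
) -> KGMLScenario:
    """Randomised but structurally valid scenario.

    Genes receive identifiers ``hsa:1001…``; a fraction of gene entries carry
    two identifiers (as real KGML gene entries often do).  Relations connect
    random entry pairs with subtypes drawn from the common KGML vocabulary,
    including compound-routed relations; ``cycle=True`` threads a directed
    gene cycle through activation relations so cyclic fixtures are certain.
    """
    rng = np.random.default_rng(seed)
    num = pathway_number if pathway_number is not None else int(rng.integers(10000, 99999))
    sc = KGMLScenario(pathway_id=f"path:syn{num:05d}", title=f"synthetic pathway {num}")
    next_id = 1

    def new_id() -> str:
        nonlocal next_id
        nid = str(next_id)
        next_id += 1
        return nid

    gene_ids, compound_ids = [], []
    for i in range(n_genes):
        names = [f"hsa:{1001 + seed % 97 * 100 + i}"]
        if rng.random() < multi_name_fraction:
            names.append(f"hsa:{9001 + seed % 97 * 100 + i}")
        eid = new_id()
        gene_ids.append(eid)
        sc.entries.append(EntrySpec(eid, "gene", names))
    for i in range(n_compounds):
        eid = new_id()
        compound_ids.append(eid)
        sc.entries.append(EntrySpec(eid, "compound", [f"cpd:C{seed % 97:03d}{i:02d}"]))
    for i in range(n_maps):
        sc.entries.append(EntrySpec(new_id(), "map", [f"path:syn{int(rng.integers(10000, 99999)):05d}"]))
    if n_groups and n_genes >= 2:
        members = [gene_ids[int(k)] for k in rng.choice(len(gene_ids), size=2, replace=False)]
        sc.entries.append(EntrySpec(new_id(), "group", [], members=members))

    relatable = [e.entry_id for e in sc.entries if e.kind in {"gene", "compound", "map", "group"}]
    subtype_pool = ["activation", "inhibition", "expression", "binding/association", "phosphorylation", ""]
    if cycle and len(gene_ids) >= 3:
        loop = [gene_ids[int(k)] for k in rng.choice(len(gene_ids), size=3, replace=False)]
        for a, b in zip(loop, loop[1:] + loop[:1]):
            sc.relations.append(RelationSpec(a, b, [("activation", "-->")]))
    for _ in range(n_relations):
        e1, e2 = (relatable[int(k)] for k in rng.choice(len(relatable), size=2, replace=False))
        pick = subtype_pool[int(rng.integers(len(subtype_pool)))]
        if compound_ids and rng.random() < 0.25:
            c = compound_ids[int(rng.integers(len(compound_ids)))]
            sc.relations.append(RelationSpec(e1, e2, [("compound", c)]))
        elif pick:
            sc.relations.append(RelationSpec(e1, e2, [(pick, "")]))
        else:
            sc.relations.append(RelationSpec(e1, e2, []))
    for i in range(n_reactions):
        if len(compound_ids) >= 2 and gene_ids:
            rname = f"rn:R{seed % 97:03d}{i:02d}"
            enzyme = gene_ids[int(rng.integers(len(gene_ids)))]
            for e in sc.entries:
                if e.entry_id == enzyme:
                    e.reactions.append(rname)
            sub, prod = (compound_ids[int(k)] for k in rng.choice(len(compound_ids), size=2, replace=False))
            sc.reactions.append(ReactionSpec(rid=enzyme, name=rname, reversible=bool(rng.random() < 0.5), substrates=[sub], products=[prod]))
    return sc


def write_fixture_dir(out_dir, n: int, seed: int, cyclic_fraction: float = 0.6) -> list[Path]:
    """Write ``n`` synthetic KGML files; roughly ``cyclic_fraction`` get a threaded cycle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = []
    for i in range(n):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sc = random_scenario(
            sub_seed,
            n_genes=int(rng.integers(7, 15)),
            n_compounds=int(rng.integers(2, 5)),
            n_relations=int(rng.integers(10, 22)),
            cycle=bool(rng.random() < cyclic_fraction),
            pathway_number=10000 + i,
        )
        p = out / f"syn{10000 + i:05d}.xml"
        p.write_text(scenario_to_kgml(sc), encoding="utf-8")
        paths.append(p)
    return paths


def random_true_dag(
    n_nodes: int,
    n_edges: int,
    seed: int,
    max_in_degree: int = 3,
) -> GeneNetwork:
    """Random DAG with bounded in-degree, for use as a data-generating truth.

    Pathway-derived regulatory structure is sparse: few genes have more than
    a handful of regulators.  The cap also keeps the generating structure
    statistically identifiable — a multinomial node with k 3-level parents
    has 3^k configurations, so at a few hundred samples nodes beyond ~3
    parents cannot repay their BIC penalty no matter how strong the
    regulation.  Edges are drawn uniformly among the forward pairs of a
    random permutation, skipping targets already at the cap.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(n_nodes)]
    perm = [genes[i] for i in rng.permutation(n_nodes)]
    pairs = [(perm[i], perm[j]) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    edges: dict[tuple[str, str], str] = {}
    indeg = {g: 0 for g in genes}
    for idx in rng.permutation(len(pairs)):
        if len(edges) == n_edges:
            break
        u, v = pairs[int(idx)]
        if indeg[v] < max_in_degree:
            edges[(u, v)] = UNKNOWN
            indeg[v] += 1
    return GeneNetwork(genes=genes, edges=edges)


def random_gene_network(
    n_nodes: int,
    n_edges: int,
    seed: int,
    ensure_cyclic: bool = False,
    signed_fraction: float = 0.0,
) -> GeneNetwork:
    """Seeded random directed network over genes g00, g01, … (no self-loops)."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(n_nodes)]
    pairs = [(u, v) for u in genes for v in genes if u != v]
    n_edges = min(n_edges, len(pairs))
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    edges = {pairs[int(c)]: UNKNOWN for c in chosen}
    if signed_fraction:
        from .network import ACTIVATING, INHIBITING

        for e in sorted(edges):
            if rng.random() < signed_fraction:
                edges[e] = ACTIVATING if rng.random() < 0.5 else INHIBITING
    g = GeneNetwork(genes=genes, edges=edges)
    if ensure_cyclic and not g.has_cycle() and n_nodes >= 2:
        nodes = [genes[int(k)] for k in rng.choice(n_nodes, size=min(3, n_nodes), replace=False)]
        for a, b in zip(nodes, nodes[1:] + nodes[:1]):
            if a != b:
                edges[(a, b)] = edges.get((a, b), UNKNOWN)
        g = GeneNetwork(genes=genes, edges=edges)
    return g
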