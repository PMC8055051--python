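"""KGML (KEGG Markup Language) ingestion.

KGML is the XML schema behind KEGG pathway maps.  A document holds *entries*
(gene, ortholog, compound, map, group, enzyme, ...), *relations* between two
entries (with subtypes such as activation or inhibition, or a "compound"
subtype routing the interaction through an explicit compound entry), and
*reactions* (substrates and products of an enzyme-catalysed step).

:func:`parse_kgml` turns a document into a typed :class:`PathwayModel`;
:func:`build_hetero_graph` flattens groups, expands multi-identifier entries
and produces the heterogeneous directed graph over concrete identifiers that
the gene-network collapse consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from lxml import etree

from .network import ACTIVATING, INHIBITING, UNKNOWN, combine_signs

logger = logging.getLogger(__name__)

ENTRY_KINDS = frozenset({"gene", "ortholog", "compound", "map", "group", "enzyme", "other"})

#: relation subtype labels implying a sign
_ACTIVATING_SUBTYPES = {"activation", "expression"}
_INHIBITING_SUBTYPES = {"inhibition", "repression"}
#: relation subtype labels with no asserted direction → edges both ways
_UNDIRECTED_SUBTYPES = {"binding/association", "dissociation"}
#: relation subtype labels routing through an explicit compound entry
_COMPOUND_SUBTYPES = {"compound", "hidden compound"}


class KGMLParseError(ValueError):
    """Malformed KGML input."""


def subtype_sign(subtype: str) -> str:
    if subtype in _ACTIVATING_SUBTYPES:
        return ACTIVATING
    if subtype in _INHIBITING_SUBTYPES:
        return INHIBITING
    return UNKNOWN


@dataclass
class PathwayEntry:
    entry_id: str
    kind: str  # one of ENTRY_KINDS
    names: list[str]
    members: list[str] = field(default_factory=list)  # entry_ids, groups only
    reactions: list[str] = field(default_factory=list)  # reaction names catalysed


@dataclass
class PathwayLink:
    source: str  # entry_id
    target: str  # entry_id
    origin: str  # relation | reaction_substrate | reaction_product
    subtype: str
    sign: str


@dataclass
class PathwayModel:
    pathway_id: str
    title: str
    entries: dict[str, PathwayEntry]
    links: list[PathwayLink]

    def validate(self) -> None:
        for link in self.links:
            if link.source not in self.entries or link.target not in self.entries:
                raise ValueError(f"link {link.source}->{link.target} references unknown entry")
        for entry in self.entries.values():
            if entry.kind == "group":
                if not entry.members:
                    raise ValueError(f"group entry {entry.entry_id} has no members")
                for m in entry.members:
                    if m not in self.entries:
                        raise ValueError(f"group {entry.entry_id} member {m} unresolved")
            elif not entry.names:
                raise ValueError(f"entry {entry.entry_id} has no names")


@dataclass
class HeteroGraph:
    """Directed graph over concrete identifiers, each tagged with a kind."""

    kinds: dict[str, str]
    edges: dict[tuple[str, str], str]

    def add_edge(self, u: str, v: str, sign: str) -> None:
        if u == v:
            return
        prev = self.edges.get((u, v))
        if prev is None:
            self.edges[(u, v)] = sign
        elif prev != sign:
            self.edges[(u, v)] = UNKNOWN

    @property
    def n_nodes(self) -> int:
        return len(self.kinds)


def parse_kgml(document: str) -> PathwayModel:
    """Parse a KGML document into a :class:`PathwayModel`.

    Unknown entry ``type`` attributes are retained with kind ``other`` (and a
    warning); relations referencing a missing entry id are skipped with a
    warning; malformed XML raises :class:`KGMLParseError` naming the line.
    """
    try:
        root = etree.fromstring(document.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise KGMLParseError(f"malformed XML at line {exc.lineno}: {exc.msg}") from exc
    if root.tag != "pathway":
        raise KGMLParseError(f"root element is <{root.tag}>, expected <pathway>")

    entries: dict[str, PathwayEntry] = {}
    for el in root.findall("entry"):
        entry_id = el.get("id")
        if entry_id is None:
            logger.warning("entry without id skipped")
            continue
        kind = el.get("type", "other")
        if kind not in ENTRY_KINDS:
            logger.warning("entry %s: unknown type %r retained as 'other'", entry_id, kind)
            kind = "other"
        names = (el.get("name") or "").split()
        members = [c.get("id") for c in el.findall("component") if c.get("id")]
        reactions = (el.get("reaction") or "").split()
        entries[entry_id] = PathwayEntry(entry_id, kind, names, members, reactions)

    links: list[PathwayLink] = []

    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        if e1 not in entries or e2 not in entries:
            logger.warning("relation %s->%s references missing entry; skipped", e1, e2)
            continue
        subtypes = [(st.get("name") or "", st.get("value") or "") for st in rel.findall("subtype")]
        plain = [(nm, val) for nm, val in subtypes if nm not in _COMPOUND_SUBTYPES]
        via_compound = [(nm, val) for nm, val in subtypes if nm in _COMPOUND_SUBTYPES]

        # aggregate sign of the relation's plain subtypes, used for compound hops
        agg = UNKNOWN
        signed = {subtype_sign(nm) for nm, _ in plain} - {UNKNOWN}
        if len(signed) == 1:
            agg = signed.pop()

        for nm, val in via_compound:
            if val in entries:
                links.append(PathwayLink(e1, val, "relation", nm, agg))
                links.append(PathwayLink(val, e2, "relation", nm, agg))
            else:
                logger.warning("relation %s->%s: compound subtype value %r unresolved; treated as direct", e1, e2, val)
                links.append(PathwayLink(e1, e2, "relation", nm, agg))
        for nm, _ in plain:
            if nm in _UNDIRECTED_SUBTYPES:
                links.append(PathwayLink(e1, e2, "relation", nm, UNKNOWN))
                links.append(PathwayLink(e2, e1, "relation", nm, UNKNOWN))
            else:
                links.append(PathwayLink(e1, e2, "relation", nm, subtype_sign(nm)))
        if not subtypes:
            links.append(PathwayLink(e1, e2, "relation", "", UNKNOWN))

    for rxn in root.findall("reaction"):
        name = rxn.get("name") or ""
        reversible = rxn.get("type") == "reversible"
        enzymes = [e.entry_id for e in entries.values() if name and name in e.reactions]
        if not enzymes and rxn.get("id") in entries:
            enzymes = [rxn.get("id")]
        if not enzymes:
            logger.warning("reaction %r has no catalysing entry; skipped", name)
            continue
        substrates = [s.get("id") for s in rxn.findall("substrate") if s.get("id") in entries]
        products = [p.get("id") for p in rxn.findall("product") if p.get("id") in entries]
        for enz in enzymes:
            for s in substrates:
                links.append(PathwayLink(s, enz, "reaction_substrate", name, UNKNOWN))
                if reversible:
                    links.append(PathwayLink(enz, s, "reaction_product", name, UNKNOWN))
            for p in products:
                links.append(PathwayLink(enz, p, "reaction_product", name, UNKNOWN))
                if reversible:
                    links.append(PathwayLink(p, enz, "reaction_substrate", name, UNKNOWN))

    model = PathwayModel(
        pathway_id=root.get("name", ""),
        title=root.get("title", ""),
        entries=entries,
        links=links,
    )
    model.validate()
    return model


def _expand(model: PathwayModel, entry_id: str, orthologs_as_genes: bool, _stack=None) -> list[tuple[str, str]]:
    """Concrete (identifier, kind) pairs an entry stands for.

    Groups flatten recursively to their members; every entry expands to one
    node per attached identifier.  Ortholog entries count as genes only when
    `orthologs_as_genes` is set.
    """
    entry = model.entries[entry_id]
    if entry.kind == "group":
        _stack = _stack or set()
        if entry_id in _stack:
            return []
        out: list[tuple[str, str]] = []
        for m in entry.members:
            out.extend(_expand(model, m, orthologs_as_genes, _stack | {entry_id}))
        return out
    kind = entry.kind
    if kind == "ortholog":
        kind = "gene" if orthologs_as_genes else "other"
    return [(name, kind) for name in entry.names]


def build_hetero_graph(model: PathwayModel, orthologs_as_genes: bool = False) -> HeteroGraph:
    """Expand a :class:`PathwayModel` into a :class:`HeteroGraph`.

    One node per concrete identifier after group flattening and multi-name
    expansion; one directed edge per link, lifted to every expanded endpoint
    pair; duplicate edges merge (conflicting signs collapse to unknown).
    """
    model.validate()
    g = HeteroGraph(kinds={}, edges={})
    expansion: dict[str, list[tuple[str, str]]] = {}
    for entry_id, entry in model.entries.items():
        nodes = _expand(model, entry_id, orthologs_as_genes)
        expansion[entry_id] = nodes
        if entry.kind == "group":
            continue  # group nodes are not emitted; members carry the links
        for name, kind in nodes:
            prev = g.kinds.get(name)
            if prev is None:
                g.kinds[name] = kind
            elif prev != kind:
                logger.warning("identifier %r appears with kinds %r and %r; keeping %r", name, prev, kind, prev)
    # group members must exist as nodes even if the group has no links
    for entry_id, entry in model.entries.items():
        if entry.kind == "group":
            for name, kind in expansion[entry_id]:
                g.kinds.setdefault(name, kind)
    for link in model.links:
        for u, _ in expansion[link.source]:
            for v, _ in expansion[link.target]:
                g.add_edge(u, v, link.sign)
    return g
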