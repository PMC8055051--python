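"""Gene-only interaction networks.

The central container is :class:`GeneNetwork`: a directed graph over gene
identifiers with an interaction sign per edge.  A network is obtained from a
heterogeneous pathway graph by :func:`collapse_to_gene_network`, which keeps a
gene→gene edge exactly when the pathway contains a directed path between the
two genes whose internal nodes (if any) are all non-gene entities (compounds,
maps, ...).  This is what turns a KEGG pathway map into a network of all
direct and indirect gene-gene interactions.

Serialization covers the two conventional text formats: Cytoscape SIF and a
tab-separated 0/1 adjacency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

ACTIVATING = "activating"
INHIBITING = "inhibiting"
UNKNOWN = "unknown"

SIGNS = (ACTIVATING, INHIBITING, UNKNOWN)

#: SIF relation token per sign, and its inverse.
_SIGN_TO_SIF = {ACTIVATING: "activation", INHIBITING: "inhibition", UNKNOWN: "interaction"}
_SIF_TO_SIGN = {v: k for k, v in _SIGN_TO_SIF.items()}


class NetworkParseError(ValueError):
    """Raised when SIF/adjacency text does not conform to the dialect."""


class ContractError(ValueError):
    """Raised when an operation is called outside its contract."""


def combine_signs(a: str, b: str) -> str:
    """Product of two interaction signs (unknown is absorbing)."""
    if a == UNKNOWN or b == UNKNOWN:
        return UNKNOWN
    return ACTIVATING if a == b else INHIBITING


@dataclass
class GeneNetwork:
    """Directed network over gene identifiers.

    Parameters
    ----------
    genes
        Ordered gene list; the order fixes adjacency-matrix rows/columns.
        May include isolated genes.
    edges
        Mapping ``(source, target) -> sign``.  Self-loops are forbidden.
    """

    genes: list[str]
    edges: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        if len(gene_set) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        for (u, v), sign in self.edges.items():
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u not in gene_set or v not in gene_set:
                raise ValueError(f"edge ({u!r}, {v!r}) has endpoint outside gene list")
            if sign not in SIGNS:
                raise ValueError(f"unknown sign {sign!r}")

    @classmethod
    def from_edges(cls, edges, genes=None) -> "GeneNetwork":
        """Build from an iterable of ``(u, v)`` or ``(u, v, sign)`` tuples."""
        edict: dict[tuple[str, str], str] = {}
        seen: list[str] = []
        seen_set: set[str] = set()

        def note(g):
            if g not in seen_set:
                seen_set.add(g)
                seen.append(g)

        for e in edges:
            u, v = e[0], e[1]
            sign = e[2] if len(e) > 2 else UNKNOWN
            note(u)
            note(v)
            edict[(u, v)] = sign
        if genes is not None:
            for g in genes:
                note(g)
        return cls(genes=seen, edges=edict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        for (u, v), sign in self.edges.items():
            g.add_edge(u, v, sign=sign)
        return g

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(list(self.genes), dict(self.edges))

    def same_structure(self, other: "GeneNetwork") -> bool:
        """Equality of gene sets and edge pairs, ignoring signs and order."""
        return set(self.genes) == set(other.genes) and set(self.edges) == set(other.edges)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return set(self.genes) == set(other.genes) and self.edges == other.edges

    # methods mirroring the module-level operations
    def nonisolated_count(self) -> int:
        return nonisolated_count(self)

    def has_cycle(self) -> bool:
        return has_cycle(self)


def collapse_to_gene_network(h) -> GeneNetwork:
    """Collapse a heterogeneous pathway graph to a gene-only network.

    An edge g1→g2 (g1 ≠ g2) is placed iff the input contains a directed path
    g1→…→g2 whose internal nodes are all non-gene.  Non-gene nodes are then
    dropped.  The sign of an indirect edge is the product of signs along the
    path when every hop is signed and all paths for the pair agree; otherwise
    unknown.  Self-loops (a gene reaching itself through non-gene nodes) are
    suppressed.

    Edge existence is decided by a per-gene traversal expanding only
    non-gene intermediates (no path enumeration).  Signs are then resolved
    per discovered pair by a depth-first walk over simple paths, restricted
    to non-gene nodes that both lie downstream of the source and upstream of
    the target, stopping as soon as the sign set saturates to unknown —
    walks that revisit a node can manufacture sign combinations no simple
    path realises, so sign resolution must stick to simple paths.
    """
    genes = sorted(n for n, kind in h.kinds.items() if kind == "gene")
    gene_set = set(genes)
    succ: dict[str, list[tuple[str, str]]] = {}
    pred: dict[str, list[str]] = {}
    for (u, v), sign in h.edges.items():
        succ.setdefault(u, []).append((v, sign))
        pred.setdefault(v, []).append(u)

    def nongene_closure(start_nodes, adjacency):
        """Non-gene nodes reachable through non-gene nodes only."""
        out: set[str] = set()
        stack = [n for n in start_nodes if n not in gene_set]
        while stack:
            n = stack.pop()
            if n in out:
                continue
            out.add(n)
            for nxt in adjacency.get(n, ()):
                m = nxt[0] if isinstance(nxt, tuple) else nxt
                if m not in gene_set and m not in out:
                    stack.append(m)
        return out

    # upstream[g2]: non-gene nodes from which g2 is reachable via non-gene nodes
    upstream: dict[str, set[str]] = {g: nongene_closure(pred.get(g, ()), pred) for g in genes}

    edges: dict[tuple[str, str], str] = {}
    for g1 in genes:
        downstream = nongene_closure([v for v, _ in succ.get(g1, ())], succ)
        targets: set[str] = {v for v, _ in succ.get(g1, ()) if v in gene_set and v != g1}
        for node in downstream:
            targets.update(v for v, _ in succ.get(node, ()) if v in gene_set and v != g1)
        for g2 in sorted(targets):
            allowed = downstream & upstream[g2]
            signs: set[str] = set()
            # DFS over simple paths g1 → (allowed non-gene nodes)* → g2
            stack: list[tuple[str, str, frozenset]] = []
            for v, s in succ.get(g1, ()):
                if v == g2:
                    signs.add(s)
                elif v in allowed:
                    stack.append((v, s, frozenset((v,))))
            while stack and not (UNKNOWN in signs or len(signs) > 1):
                node, acc, visited = stack.pop()
                for v, s in succ.get(node, ()):
                    combined = combine_signs(acc, s)
                    if v == g2:
                        signs.add(combined)
                        if UNKNOWN in signs or len(signs) > 1:
                            break
                    elif v in allowed and v not in visited:
                        stack.append((v, combined, visited | {v}))
            if signs:
                edges[(g1, g2)] = signs.pop() if len(signs) == 1 else UNKNOWN

    return GeneNetwork(genes=genes, edges=edges)


def nonisolated_count(g: GeneNetwork) -> int:
    """Number of genes with in-degree + out-degree ≥ 1."""
    touched = set()
    for u, v in g.edges:
        touched.add(u)
        touched.add(v)
    return len(touched)


def has_cycle(g: GeneNetwork) -> bool:
    """True iff a directed cycle (length ≥ 2; self-loops cannot occur) exists."""
    return not nx.is_directed_acyclic_graph(g.to_networkx())


def serialize_network(g: GeneNetwork, format: str) -> str:
    """Write a network as SIF or as a 0/1 adjacency matrix.

    SIF: one ``source<TAB>relation<TAB>target`` line per edge (relation is
    activation/inhibition/interaction), isolated genes as bare one-token
    lines.  Adjacency: first row and column carry the gene names in ``genes``
    order; cells are 1 if row→column is an edge.
    """
    if format == "sif":
        lines = []
        for (u, v) in sorted(g.edges):
            lines.append(f"{u}\t{_SIGN_TO_SIF[g.edges[(u, v)]]}\t{v}")
        touched = {x for e in g.edges for x in e}
        for gene in g.genes:
            if gene not in touched:
                lines.append(gene)
        return "\n".join(lines) + ("\n" if lines else "")
    if format == "adjacency":
        header = "\t" + "\t".join(g.genes)
        rows = [header]
        for u in g.genes:
            cells = ["1" if (u, v) in g.edges else "0" for v in g.genes]
            rows.append(u + "\t" + "\t".join(cells))
        return "\n".join(rows) + "\n"
    raise ValueError(f"unsupported format {format!r} (expected 'sif' or 'adjacency')")


def parse_network(text: str, format: str) -> GeneNetwork:
    """Inverse of :func:`serialize_network` on its image."""
    if format == "sif":
        genes: list[str] = []
        seen: set[str] = set()
        edges: dict[tuple[str, str], str] = {}

        def note(gene):
            if gene not in seen:
                seen.add(gene)
                genes.append(gene)

        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                note(parts[0])
            elif len(parts) == 3:
                u, rel, v = parts
                note(u)
                note(v)
                edges[(u, v)] = _SIF_TO_SIGN.get(rel, UNKNOWN)
            else:
                raise NetworkParseError(f"line {lineno}: expected 1 or 3 tab-separated fields, got {len(parts)}")
        return GeneNetwork(genes=genes, edges=edges)
    if format == "adjacency":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            return GeneNetwork(genes=[], edges={})
        header = lines[0].split("\t")
        if header[0] != "":
            raise NetworkParseError("line 1: adjacency header must start with an empty cell")
        genes = header[1:]
        n = len(genes)
        if len(lines) - 1 != n:
            raise NetworkParseError(f"expected {n} data rows, got {len(lines) - 1}")
        edges: dict[tuple[str, str], str] = {}
        for i, line in enumerate(lines[1:], start=2):
            parts = line.split("\t")
            if len(parts) != n + 1:
                raise NetworkParseError(f"line {i}: ragged row ({len(parts)} cells, expected {n + 1})")
            if parts[0] != genes[i - 2]:
                raise NetworkParseError(f"line {i}: row label {parts[0]!r} does not match header order")
            for j, cell in enumerate(parts[1:]):
                if cell == "1":
                    edges[(parts[0], genes[j])] = UNKNOWN
                elif cell != "0":
                    raise NetworkParseError(f"line {i}: non-binary cell {cell!r}")
        return GeneNetwork(genes=list(genes), edges=edges)
    raise ValueError(f"unsupported format {format!r} (expected 'sif' or 'adjacency')")
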