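"""Shared data model and file I/O: dated trees, gene-order tables, taxon groups.

Trees are stored in a flat, post-order-indexed node array so that branch event
tables and rate tables are reproducible across runs.  Branch lengths carry
either durations in million years (``units="my"``, a chronogram) or
substitutions per site (``units="subs"``).  Coordinates in gene tables are
1-based inclusive, GenBank style.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import dendropy

MY = "my"
SUBS = "subs"

GROUPS = frozenset(
    {
        "magnoliid",
        "gymnosperm_outgroup",
        "monocot_grass",
        "monocot_nongrass",
        "eudicot_rosid",
        "eudicot_asterid",
        "eudicot_other",
    }
)
MONOCOT_GROUPS = frozenset({"monocot_grass", "monocot_nongrass"})
EUDICOT_GROUPS = frozenset({"eudicot_rosid", "eudicot_asterid", "eudicot_other"})


class TreeError(ValueError):
    pass


@dataclass
class TreeNode:
    id: int
    parent: int | None
    children: tuple[int, ...]
    label: str | None = None
    length: float | None = None  # duration (My) or subs/site on the branch above


@dataclass
class DatedTree:
    """Rooted tree with per-branch lengths; node ids are post-order indices."""

    nodes: list[TreeNode]
    root: int
    units: str = MY

    # -- basic structure -------------------------------------------------
    @property
    def leaves(self) -> list[int]:
        return [n.id for n in self.nodes if not n.children]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.nodes[i].label for i in self.leaves]

    def leaf_id(self, label: str) -> int:
        for i in self.leaves:
            if self.nodes[i].label == label:
                return i
        raise KeyError(label)

    def branch_ids(self) -> list[int]:
        """Every non-root node id, i.e. every branch (identified by its child)."""
        return [n.id for n in self.nodes if n.parent is not None]

    def postorder(self) -> list[int]:
        return [n.id for n in self.nodes]  # ids are assigned in post-order

    def preorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.nodes[v].children))
        return order

    def subtree_leaves(self, node: int) -> list[int]:
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if not self.nodes[v].children:
                out.append(v)
            else:
                stack.extend(self.nodes[v].children)
        return out

    def mrca(self, node_ids: list[int]) -> int:
        if not node_ids:
            raise TreeError("mrca of empty set")
        paths = []
        for v in node_ids:
            path = []
            while v is not None:
                path.append(v)
                v = self.nodes[v].parent
            paths.append(list(reversed(path)))
        anc = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            step = {p[depth] for p in paths}
            if len(step) == 1:
                anc = step.pop()
            else:
                break
        return anc

    def path_branches(self, leaf_a: int, leaf_b: int) -> list[int]:
        """Branch ids (child-node ids) on the path between two leaves."""
        anc = self.mrca([leaf_a, leaf_b])
        out = []
        for v in (leaf_a, leaf_b):
            while v != anc:
                out.append(v)
                v = self.nodes[v].parent
        return out

    def depth(self, node: int) -> float:
        d = 0.0
        v = node
        while self.nodes[v].parent is not None:
            d += self.nodes[v].length or 0.0
            v = self.nodes[v].parent
        return d

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = [self.depth(v) for v in self.leaves]
        top = max(depths)
        if top == 0:
            return True
        return all(abs(d - top) <= rel_tol * top for d in depths)

    def clade_key(self, node: int) -> frozenset[str]:
        """Leaf-label set below a node; used to match branches across trees."""
        return frozenset(self.nodes[v].label for v in self.subtree_leaves(node))

    def scale(self, factor: float) -> "DatedTree":
        nodes = [
            replace(n, length=None if n.length is None else n.length * factor)
            for n in self.nodes
        ]
        return DatedTree(nodes, self.root, self.units)

    # -- serialisation ---------------------------------------------------
    def to_newick(self) -> str:
        def render(v: int) -> str:
            node = self.nodes[v]
            if node.children:
                inner = ",".join(render(c) for c in node.children)
                body = f"({inner})"
            else:
                body = node.label or ""
            if node.parent is None:
                return body
            length = node.length
            return body if length is None else f"{body}:{length:g}"

        return render(self.root) + ";"


def parse_dated_tree(
    newick_text: str, units: str = MY, require_ultrametric: bool = False
) -> DatedTree:
    """Parse a Newick string into a :class:`DatedTree`.

    ``units="my"`` requires a branch length on every non-root branch (a
    chronogram with durations in million years); ``units="subs"`` tolerates
    missing lengths.  Internal nodes get deterministic post-order ids.
    """
    if units not in (MY, SUBS):
        raise TreeError(f"unknown units {units!r}")
    try:
        dtree = dendropy.Tree.get(
            data=newick_text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"invalid Newick: {exc}") from exc

    labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise TreeError("duplicate leaf labels")

    nodes: list[TreeNode] = []
    index: dict[int, int] = {}
    for dn in dtree.postorder_node_iter():
        idx = len(nodes)
        index[id(dn)] = idx
        children = tuple(index[id(c)] for c in dn.child_nodes())
        label = dn.taxon.label if dn.taxon is not None else None
        length = dn.edge.length
        if length is not None and length < 0:
            raise TreeError(f"negative branch length {length}")
        nodes.append(TreeNode(idx, None, children, label, length))
    root = len(nodes) - 1
    for n in nodes:
        for c in n.children:
            nodes[c] = replace(nodes[c], parent=n.id)
    tree = DatedTree(nodes, root, units)
    if units == MY:
        for b in tree.branch_ids():
            if nodes[b].length is None:
                raise TreeError(f"missing branch length on node {b} (units=my)")
    if require_ultrametric and not tree.is_ultrametric():
        raise TreeError("tree flagged ultrametric but leaf depths differ")
    return tree


# ---------------------------------------------------------------------------
# Gene order tables


class GeneTableError(ValueError):
    pass


@dataclass(frozen=True)
class Gene:
    name: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    pseudogene: bool = False


@dataclass
class GeneOrderRecord:
    species: str
    genome_length: int
    topology: str  # 'circular' | 'linear'
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise GeneTableError(f"unknown topology {self.topology!r}")
        for g in self.genes:
            if not (1 <= g.start <= g.end <= self.genome_length):
                raise GeneTableError(
                    f"{g.name}: coordinates {g.start}..{g.end} outside "
                    f"[1, {self.genome_length}]"
                )
            if g.strand not in ("+", "-"):
                raise GeneTableError(f"{g.name}: unknown strand {g.strand!r}")
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.name))
        seen = set()
        for g in self.genes:
            key = (g.name, g.start)
            if key in seen:
                raise GeneTableError(f"duplicate gene entry {key}")
            seen.add(key)


def parse_gene_table(tsv_text: str) -> GeneOrderRecord:
    """Parse the two-header gene table format.

    Line 1: ``species genome_length topology`` header; line 2: its values;
    line 3: ``gene start end strand pseudogene`` header; then one gene per row.
    """
    lines = [ln for ln in tsv_text.splitlines() if ln.strip()]
    if len(lines) < 3:
        raise GeneTableError("truncated gene table")
    if lines[0].split("\t") != ["species", "genome_length", "topology"]:
        raise GeneTableError(f"bad record header: {lines[0]!r}")
    species, length_s, topology = lines[1].split("\t")
    if lines[2].split("\t") != ["gene", "start", "end", "strand", "pseudogene"]:
        raise GeneTableError(f"bad gene header: {lines[2]!r}")
    genes = []
    for ln in lines[3:]:
        name, start_s, end_s, strand, pseudo_s = ln.split("\t")
        start, end = int(start_s), int(end_s)
        if end < start:
            raise GeneTableError(f"{name}: end {end} < start {start}")
        if pseudo_s not in ("0", "1"):
            raise GeneTableError(f"{name}: pseudogene flag must be 0/1")
        genes.append(Gene(name, start, end, strand, pseudo_s == "1"))
    return GeneOrderRecord(species, int(length_s), topology, genes)


def write_gene_table(record: GeneOrderRecord) -> str:
    buf = io.StringIO()
    buf.write("species\tgenome_length\ttopology\n")
    buf.write(f"{record.species}\t{record.genome_length}\t{record.topology}\n")
    buf.write("gene\tstart\tend\tstrand\tpseudogene\n")
    for g in record.genes:
        buf.write(
            f"{g.name}\t{g.start}\t{g.end}\t{g.strand}\t{int(g.pseudogene)}\n"
        )
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Taxon groups


@dataclass
class TaxonGroups:
    """Map taxon name -> major-clade group label."""

    groups: dict[str, str]

    def __post_init__(self) -> None:
        for taxon, grp in self.groups.items():
            if grp not in GROUPS:
                raise ValueError(f"{taxon}: unknown group {grp!r}")

    def __getitem__(self, taxon: str) -> str:
        return self.groups[taxon]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.groups

    def is_monocot(self, taxon: str) -> bool:
        return self.groups[taxon] in MONOCOT_GROUPS

    def is_eudicot(self, taxon: str) -> bool:
        return self.groups[taxon] in EUDICOT_GROUPS


def parse_taxon_groups(tsv_text: str) -> TaxonGroups:
    groups = {}
    for ln in tsv_text.splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        taxon, grp = ln.split("\t")
        if taxon in groups:
            raise ValueError(f"taxon {taxon!r} listed twice")
        groups[taxon] = grp
    return TaxonGroups(groups)


def write_taxon_groups(groups: TaxonGroups) -> str:
    return "".join(f"{t}\t{g}\n" for t, g in groups.groups.items())
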