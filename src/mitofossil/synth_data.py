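"""Seeded generators for synthetic inputs with the statistical structure the
analyses assume.

Each generator returns its dataset together with a :class:`SimTruth` carrying
the generating parameters and the per-branch true events/rates, sufficient to
score downstream inference without re-simulation.  All randomness flows
through an explicit integer seed; a fixed seed reproduces the dataset bit for
bit.

What is emulated: Yule chronograms with durations in million years; edit-site
presence/absence evolving under single-origin dynamics (sites present in the
ancestor are lost along branches as Poisson events — loss is absorbing — and
new sites arise once each at a gain rate), with block-wise missing data per
taxon x gene; codon alignments whose third positions diverge by a specified
per-branch synonymous amount while nonsynonymous positions stay fixed; gene
orders derived from a common ancestor by random inversions whose breakpoints
either avoid or may break planted adjacencies; and plastid-insert alignment
pairs with a conserved island inside diverged, indel-bearing flanks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import MY, DatedTree, Gene, GeneOrderRecord, parse_dated_tree
from .edit_calling import (
    EXCL_NONE,
    EditMatrix,
    SITE_FIELDS,
    classify_edit_effect,
)
from .silent_rates import CodonAlignment


@dataclass
class SimTruth:
    """Generating parameters plus per-item true events/rates."""

    generator: str
    params: dict
    records: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"generator": self.generator, "params": self.params, "records": self.records},
            indent=2,
            default=str,
        )


# ---------------------------------------------------------------------------
# Trees


def simulate_dated_tree(n_taxa: int, crown_age: float, seed: int) -> DatedTree:
    """Yule (pure-birth) chronogram with the crown scaled to ``crown_age`` My.

    Forward simulation: the crown splits into two lineages at time 0, each
    subsequent split hits a uniformly chosen extant lineage after an
    exponential wait, and after the n-th lineage appears the process runs for
    one further waiting time before the present is cut — so every branch has
    strictly positive duration.  Ultrametric by construction; leaves are
    labeled T1..Tn.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)

    class _N:
        __slots__ = ("birth", "end", "children")

        def __init__(self, birth):
            self.birth = birth
            self.end = None
            self.children = []

    root = _N(0.0)
    root.children = [_N(0.0), _N(0.0)]
    active = list(root.children)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        node.end = t
        node.children = [_N(t), _N(t)]
        active.extend(node.children)
    t_end = t + rng.exponential(1.0 / n_taxa)
    for node in active:
        node.end = t_end

    counter = {"i": 0}

    def render(node: _N) -> str:
        length = (node.end if node.children == [] else node.children[0].birth) - node.birth
        if node.children:
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}):{length:.12g}"
        counter["i"] += 1
        return f"T{counter['i']}:{length:.12g}"

    newick = "(" + ",".join(render(c) for c in root.children) + ");"
    tree = parse_dated_tree(newick, units=MY)
    tree = tree.scale(crown_age / t_end)
    # pin every leaf depth exactly at crown_age (remove float drift)
    for v in tree.leaves:
        node = tree.nodes[v]
        slack = crown_age - tree.depth(v)
        tree.nodes[v] = type(node)(
            node.id, node.parent, node.children, node.label,
            node.length + slack,
        )
    return tree


# ---------------------------------------------------------------------------
# Edit matrices

# codons with a C at each position, used to give simulated sites a codon context
_C_CODONS = {
    pos: [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if (a + b + c)[pos - 1] == "C" and (a + b + c) not in ("TAA", "TGA", "TAG")
    ]
    for pos in (1, 2, 3)
}


def simulate_edit_matrix(
    tree: DatedTree,
    n_ancestral_sites: int = 700,
    loss_rate: float = 0.004,
    gain_rate: float = 0.0005,
    missing_frac: float = 0.1,
    seed: int = 0,
    n_genes: int = 5,
    branch_loss_scale: dict[int, float] | None = None,
) -> tuple[EditMatrix, SimTruth]:
    """Evolve 0/1/? edit-site columns on a chronogram.

    Ancestral sites are present at the root and lost along branches as
    Poisson events with rate ``loss_rate`` per My (absorbing); new sites
    arise once each at ``gain_rate`` per My per branch.  Lineage-specific
    loss regimes are modeled by ``branch_loss_scale`` multipliers (per branch
    id).  Missing data is assigned per taxon x gene block with probability
    ``missing_frac``.  Sites observed in no taxon (extinct or fully masked)
    are dropped, as the matrix only holds columns edited somewhere; the drop
    count is in truth.
    """
    rng = np.random.default_rng(seed)
    scale = branch_loss_scale or {}
    branch_ids = tree.branch_ids()
    durations = {v: tree.nodes[v].length or 0.0 for v in branch_ids}
    loss_rates = {v: loss_rate * scale.get(v, 1.0) for v in branch_ids}

    # sites: (origin_node, dict leaf->0/1, loss_branches)
    sites = []
    for _ in range(n_ancestral_sites):
        sites.append({"origin": tree.root})
    for v in branch_ids:
        n_new = rng.poisson(gain_rate * durations[v])
        for _ in range(n_new):
            sites.append({"origin": v})

    leaf_ids = tree.leaves
    for site in sites:
        present = {site["origin"]: True}
        losses = []
        for v in tree.preorder():
            if v == site["origin"]:
                continue
            parent = tree.nodes[v].parent
            if parent is None or not present.get(parent, False):
                present[v] = present.get(v, False)
                continue
            lost = rng.random() < 1.0 - math.exp(-loss_rates[v] * durations[v])
            present[v] = not lost
            if lost:
                losses.append(v)
        site["losses"] = losses
        site["leaf_states"] = {
            tree.nodes[v].label: int(present.get(v, False)) for v in leaf_ids
        }

    taxa = sorted(tree.leaf_labels)
    genes = [f"g{k + 1}" for k in range(n_genes)]
    missing = {
        (taxon, gene): bool(rng.random() < missing_frac)
        for taxon in taxa
        for gene in genes
    }

    per_gene_counter = {g: 0 for g in genes}
    rows, meta, index = [], [], []
    truth_sites = {}
    n_dropped = 0
    for j, site in enumerate(sites):
        gene = genes[j % n_genes]
        cells = {}
        observed_one = False
        for taxon in taxa:
            if missing[(taxon, gene)]:
                cells[taxon] = "?"
            else:
                state = site["leaf_states"][taxon]
                cells[taxon] = str(state)
                observed_one = observed_one or state == 1
        if not observed_one:
            n_dropped += 1
            continue
        per_gene_counter[gene] += 1
        codon_index = per_gene_counter[gene]
        codon_pos = int(rng.integers(1, 4))
        ref_codon = _C_CODONS[codon_pos][rng.integers(len(_C_CODONS[codon_pos]))]
        column = (codon_index - 1) * 3 + codon_pos
        site_id = f"{gene}.{column}"
        rows.append(cells)
        meta.append(
            {
                "gene": gene,
                "column": column,
                "codon_index": codon_index,
                "codon_pos": codon_pos,
                "ref_codon": ref_codon,
                "effect": classify_edit_effect(ref_codon, codon_pos),
                "excl_reason": EXCL_NONE,
            }
        )
        index.append(site_id)
        truth_sites[site_id] = {
            "origin": site["origin"],
            "losses": site["losses"],
        }

    cells_df = pd.DataFrame(rows, index=index, columns=taxa, dtype=str)
    sites_df = pd.DataFrame(meta, index=index, columns=SITE_FIELDS)
    matrix = EditMatrix(cells_df, sites_df, dropped_all_zero=n_dropped)
    truth = SimTruth(
        "edit_matrix",
        {
            "n_ancestral_sites": n_ancestral_sites,
            "loss_rate": loss_rate,
            "gain_rate": gain_rate,
            "missing_frac": missing_frac,
            "seed": seed,
            "n_genes": n_genes,
        },
        {
            "sites": truth_sites,
            "n_dropped_unobserved": n_dropped,
            "true_losses_retained": sum(
                len(s["losses"]) for s in truth_sites.values()
            ),
            "true_gains_retained": sum(
                1 for s in truth_sites.values() if s["origin"] != tree.root
            ),
        },
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Codon alignments

# codon families whose third position is fully synonymous and whose first two
# positions admit no synonymous single changes (NG86 syn sites = exactly 1)
_SYN1_PREFIXES = ["TC", "CC", "AC", "GC", "GT", "GG"]
_BASES = "TCAG"


def simulate_codon_alignment(
    tree: DatedTree,
    per_branch_ds: dict[int, float],
    n_codons: int,
    seed: int = 0,
) -> tuple[CodonAlignment, SimTruth]:
    """Evolve codons so expected synonymous divergence per branch is
    ``per_branch_ds`` (keyed by branch id).

    Ancestral codons are drawn from four-fold-degenerate families; third
    positions evolve under Jukes–Cantor with branch length equal to the
    branch's dS, and first/second positions are held fixed, isolating
    synonymous divergence.  The ancestral sequence is stop-free.
    """
    rng = np.random.default_rng(seed)
    for v, d in per_branch_ds.items():
        if d < 0:
            raise ValueError(f"negative dS on branch {v}")
    prefixes = [ _SYN1_PREFIXES[i] for i in rng.integers(len(_SYN1_PREFIXES), size=n_codons) ]
    third = rng.integers(4, size=n_codons)

    seqs_third = {tree.root: third}
    for v in tree.preorder():
        if v == tree.root:
            continue
        parent_third = seqs_third[tree.nodes[v].parent]
        d = per_branch_ds.get(v, 0.0)
        p_diff = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
        change = rng.random(n_codons) < p_diff
        new = parent_third.copy()
        if change.any():
            shifts = rng.integers(1, 4, size=int(change.sum()))
            new[change] = (new[change] + shifts) % 4
        seqs_third[v] = new

    def render(third_arr: np.ndarray) -> str:
        return "".join(
            p + _BASES[t] for p, t in zip(prefixes, third_arr)
        )

    taxa = sorted(tree.leaf_labels)
    seqs = {tree.nodes[v].label: render(seqs_third[v]) for v in tree.leaves}
    aln = CodonAlignment(taxa, seqs)
    truth = SimTruth(
        "codon_alignment",
        {"n_codons": n_codons, "seed": seed},
        {"per_branch_ds": {str(k): v for k, v in per_branch_ds.items()}},
    )
    return aln, truth


# ---------------------------------------------------------------------------
# Gene orders


def _record_layout(record: GeneOrderRecord):
    """Decompose a record into gene (name, length, strand, pseudo) and gaps."""
    genes = [
        (g.name, g.end - g.start + 1, g.strand, g.pseudogene) for g in record.genes
    ]
    gaps = [
        record.genes[i + 1].start - record.genes[i].end - 1
        for i in range(len(record.genes) - 1)
    ]
    lead = record.genes[0].start - 1
    return genes, gaps, lead


def _layout_record(
    species: str, genome_length: int, topology: str, genes, gaps, lead
) -> GeneOrderRecord:
    out = []
    pos = lead + 1
    for i, (name, length, strand, pseudo) in enumerate(genes):
        out.append(Gene(name, pos, pos + length - 1, strand, pseudo))
        if i < len(gaps):
            pos += length + gaps[i]
        else:
            pos += length
    return GeneOrderRecord(species, genome_length, topology, out)


def simulate_gene_orders(
    ancestral: GeneOrderRecord,
    tree: DatedTree,
    inversions_per_branch: float,
    protected: list[tuple[str, str]] | None = None,
    seed: int = 0,
) -> tuple[dict[str, GeneOrderRecord], SimTruth]:
    """Derive per-species gene orders from a common ancestor by inversions.

    Each branch receives Poisson(``inversions_per_branch``) inversions of a
    contiguous gene run (genes reversed, strands flipped; internal gaps
    travel with the segment, boundary gaps stay in place, so gap sizes are
    conserved as a multiset).  When ``protected`` adjacencies are given,
    breakpoints avoid falling between a currently adjacent protected pair.
    Truth records which protected adjacencies survive in each species.
    """
    rng = np.random.default_rng(seed)
    protected = protected or []
    prot_set = {frozenset(p) for p in protected}
    genes0, gaps0, lead0 = _record_layout(ancestral)

    def protected_cuts(genes) -> set[int]:
        cuts = set()
        for i in range(1, len(genes)):
            if frozenset((genes[i - 1][0], genes[i][0])) in prot_set:
                cuts.add(i)
        return cuts

    def invert(genes, gaps, i, j):
        """Invert genes[i:j] (0-based, j exclusive), i < j."""
        seg = [(n, L, "-" if s == "+" else "+", p) for (n, L, s, p) in genes[i:j]]
        seg.reverse()
        new_genes = genes[:i] + seg + genes[j:]
        inner = gaps[i : j - 1]
        new_gaps = gaps[: i] + inner[::-1] + gaps[j - 1 :]
        return new_genes, new_gaps

    state = {tree.root: (genes0, gaps0)}
    for v in tree.preorder():
        if v == tree.root:
            continue
        genes, gaps = state[tree.nodes[v].parent]
        genes, gaps = list(genes), list(gaps)
        n_inv = rng.poisson(inversions_per_branch)
        n = len(genes)
        for _ in range(n_inv):
            forbidden = protected_cuts(genes)
            allowed = [c for c in range(n + 1) if c not in forbidden]
            if len(allowed) < 2:
                break
            for _attempt in range(200):
                a, b = rng.choice(allowed, size=2, replace=False)
                i, j = (a, b) if a < b else (b, a)
                if j - i < n:  # skip full-genome inversion (a relabeling)
                    break
            else:
                continue
            genes, gaps = invert(genes, gaps, i, j)
        state[v] = (genes, gaps)

    records = {}
    surviving = {}
    for v in tree.leaves:
        label = tree.nodes[v].label
        genes, gaps = state[v]
        records[label] = _layout_record(
            label, ancestral.genome_length, ancestral.topology, genes, gaps, lead0
        )
        alive = []
        for i in range(1, len(genes)):
            key = frozenset((genes[i - 1][0], genes[i][0]))
            if key in prot_set and gaps[i - 1] < 5000:
                alive.append(sorted(key))
        surviving[label] = alive
    truth = SimTruth(
        "gene_orders",
        {
            "inversions_per_branch": inversions_per_branch,
            "protected": [sorted(p) for p in protected],
            "seed": seed,
        },
        {"surviving_protected": surviving},
    )
    return records, truth


# ---------------------------------------------------------------------------
# Plastid-insert pairs


def simulate_plastid_insert(
    length: int,
    island: tuple[int, int],
    island_identity: float,
    flank_identity: float,
    seed: int = 0,
) -> tuple[tuple[str, str], SimTruth]:
    """Aligned plastid/mitochondrial pair with a conserved internal island.

    Per alignment column, a divergence event occurs with probability
    1 − identity/100 (island vs flank rate); 75% of events are substitutions
    and 25% single-column indels (gap placed in one of the two sequences at
    random), matching the indels-count-as-mismatches identity convention.
    """
    if not (1 <= island[0] <= island[1] <= length):
        raise ValueError("island outside [1, length]")
    for x in (island_identity, flank_identity):
        if not (0.0 <= x <= 100.0):
            raise ValueError("identities must be in [0, 100]")
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    cp, mt = [], []
    for col in range(1, length + 1):
        in_island = island[0] <= col <= island[1]
        ident = island_identity if in_island else flank_identity
        base = bases[rng.integers(4)]
        if rng.random() < 1.0 - ident / 100.0:
            if rng.random() < 0.25:
                if rng.random() < 0.5:
                    cp.append(base)
                    mt.append("-")
                else:
                    cp.append("-")
                    mt.append(base)
            else:
                alt = bases[(bases.index(base) + 1 + rng.integers(3)) % 4]
                cp.append(base)
                mt.append(alt)
        else:
            cp.append(base)
            mt.append(base)
    pair = ("".join(cp), "".join(mt))
    truth = SimTruth(
        "plastid_insert",
        {
            "length": length,
            "island": list(island),
            "island_identity": island_identity,
            "flank_identity": flank_identity,
            "seed": seed,
        },
        {
            "realized_matches": sum(a == b and a != "-" for a, b in zip(*pair)),
        },
    )
    return pair, truth
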