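"""Colinear gene-cluster extraction, cross-species comparison and ancestral
assignment.

A cluster is two or more adjacent genes separated by fewer than ``max_gap``
(default 5 kb) of intergenic sequence with no intervening genes; pseudogenes
participate.  Clusters longer than two genes are decomposed into their
adjacent two-gene subclusters for cross-species comparison.  A pair is
canonicalized by orienting the lexicographically smaller gene name first and
recording whether the two genes lie on the same or opposite strands — making
presence symmetric under reverse-complementing a genome, which "same relative
orientation" requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .core_io import GeneOrderRecord, TaxonGroups

SAME = "same_strand"
OPPOSITE = "opposite_strand"

ANCESTRAL = "ancestral_angiosperm"
EUDICOT_PANEL = "eudicot_panel"
MONOCOT_PANEL = "monocot_panel"
OPPOSITE_PANEL = "opposite_strand_panel"
UNREPORTED = "unreported"


@dataclass(frozen=True)
class Cluster:
    """An ordered run of >=2 adjacent genes with per-pair relative orientation."""

    genes: tuple[str, ...]
    strands: tuple[str, ...]
    species: str

    def __post_init__(self) -> None:
        if len(self.genes) < 2 or len(self.genes) != len(self.strands):
            raise ValueError("cluster needs >=2 genes with matching strands")

    @property
    def pair_orientations(self) -> tuple[str, ...]:
        return tuple(
            SAME if a == b else OPPOSITE
            for a, b in zip(self.strands, self.strands[1:])
        )


@dataclass(frozen=True, order=True)
class PairKey:
    """Canonical identity of a two-gene cluster (strand-symmetric)."""

    first: str
    second: str
    orientation: str  # same_strand | opposite_strand

    @property
    def label(self) -> str:
        sep = "-" if self.orientation == SAME else "><"
        return f"{self.first}{sep}{self.second}"


def canonical_pair(gene_a: str, gene_b: str, strand_a: str, strand_b: str) -> PairKey:
    """Canonical form: lexicographically smaller gene first, relative orientation.

    The relative orientation (same/opposite strand) is invariant under reading
    the genome from the other strand, so canonicalization is an involution
    fixed point.
    """
    orientation = SAME if strand_a == strand_b else OPPOSITE
    if gene_a <= gene_b:
        return PairKey(gene_a, gene_b, orientation)
    return PairKey(gene_b, gene_a, orientation)


def extract_clusters(record: GeneOrderRecord, max_gap: int = 5000) -> list[Cluster]:
    """Maximal runs of adjacent genes with intergenic gaps < ``max_gap``.

    Circular genomes also test the wrap-around adjacency between the last and
    first genes.  Overlapping genes (negative gap) are treated as gap 0 with a
    warning.
    """
    genes = record.genes
    if len(genes) < 2:
        return []

    def gap(prev, nxt, wrap=False):
        if wrap:
            g = record.genome_length - prev.end + nxt.start - 1
        else:
            g = nxt.start - prev.end - 1
        if g < 0:
            warnings.warn(
                f"{record.species}: genes {prev.name}/{nxt.name} overlap; "
                "treating gap as 0",
                stacklevel=3,
            )
            g = 0
        return g

    runs: list[list[int]] = [[0]]
    for i in range(1, len(genes)):
        if gap(genes[i - 1], genes[i]) < max_gap:
            runs[-1].append(i)
        else:
            runs.append([i])
    if (
        record.topology == "circular"
        and len(runs) > 1
        and gap(genes[-1], genes[0], wrap=True) < max_gap
    ):
        last = runs.pop()
        runs[0] = last + runs[0]
    elif (
        record.topology == "circular"
        and len(runs) == 1
        and len(runs[0]) == len(genes)
        and gap(genes[-1], genes[0], wrap=True) < max_gap
    ):
        pass  # fully clustered circle: one run, wrap adjacency implicit

    out = []
    for run in runs:
        if len(run) >= 2:
            out.append(
                Cluster(
                    tuple(genes[i].name for i in run),
                    tuple(genes[i].strand for i in run),
                    record.species,
                )
            )
    return out


def decompose_to_pairs(cluster: Cluster) -> list[Cluster]:
    """All adjacent two-gene subclusters of a cluster."""
    return [
        Cluster(cluster.genes[i : i + 2], cluster.strands[i : i + 2], cluster.species)
        for i in range(len(cluster.genes) - 1)
    ]


def species_pair_set(clusters: list[Cluster]) -> set[PairKey]:
    """Canonical pair presence for one species (duplicates collapse)."""
    pairs = set()
    for cl in clusters:
        for sub in decompose_to_pairs(cl):
            pairs.add(
                canonical_pair(sub.genes[0], sub.genes[1], sub.strands[0], sub.strands[1])
            )
    return pairs


@dataclass
class PresenceGrid:
    """Canonical two-gene clusters x species presence, with panel assignment."""

    presence: pd.DataFrame  # bool, index PairKey labels, columns species
    pairs: dict[str, PairKey]  # label -> key
    assignment: pd.Series | None = None  # label -> panel

    def carriers(self, label: str) -> list[str]:
        row = self.presence.loc[label]
        return list(row.index[row])

    def to_tsv(self) -> str:
        df = self.presence.astype(int).copy()
        if self.assignment is not None:
            df["panel"] = self.assignment
        return df.to_csv(sep="\t", index_label="pair")


def conserved_clusters(
    per_species: dict[str, list[Cluster]],
    groups: TaxonGroups,
    anchors: tuple[str, str],
) -> PresenceGrid:
    """Cross-species presence grid under the reporting rules.

    ``anchors`` is (basal_taxon, outgroup_taxon) — the magnoliid anchor and the
    gymnosperm outgroup.  A canonical pair is reported iff it is present, in
    the same canonical relative orientation, in an anchor plus at least one
    monocot or eudicot; or, if absent from both anchors, shared between a
    monocot and a eudicot, a grass and a non-grass monocot, or an asterid and
    a rosid.
    """
    basal, outgroup = anchors
    for sp in per_species:
        if sp not in groups:
            raise ValueError(f"species {sp!r} absent from taxon groups")
    for anchor in anchors:
        if anchor not in groups:
            raise ValueError(f"anchor {anchor!r} absent from taxon groups")

    presence_sets = {sp: species_pair_set(cls) for sp, cls in per_species.items()}
    all_pairs = sorted(set().union(*presence_sets.values()) if presence_sets else set())
    species = sorted(per_species)

    reported: list[PairKey] = []
    for pair in all_pairs:
        carriers = {sp for sp in species if pair in presence_sets[sp]}
        in_anchor = basal in carriers or outgroup in carriers
        mono = {sp for sp in carriers if groups.is_monocot(sp)}
        eudi = {sp for sp in carriers if groups.is_eudicot(sp)}
        if in_anchor and (mono or eudi):
            reported.append(pair)
            continue
        if not in_anchor:
            grass = {sp for sp in mono if groups[sp] == "monocot_grass"}
            nongrass = mono - grass
            asterid = {sp for sp in eudi if groups[sp] == "eudicot_asterid"}
            rosid = {sp for sp in eudi if groups[sp] == "eudicot_rosid"}
            if (mono and eudi) or (grass and nongrass) or (asterid and rosid):
                reported.append(pair)
    labels = [p.label for p in reported]
    data = {
        sp: [pair in presence_sets[sp] for pair in reported] for sp in species
    }
    presence = pd.DataFrame(data, index=labels, columns=species, dtype=bool)
    return PresenceGrid(presence, dict(zip(labels, reported)))


def assign_ancestral_node(
    grid: PresenceGrid, groups: TaxonGroups, anchors: tuple[str, str]
) -> PresenceGrid:
    """Assign each reported pair to a panel.

    ``ancestral_angiosperm`` when carriers span at least two of {magnoliid,
    monocots, eudicots}, or include the gymnosperm outgroup plus any
    angiosperm; otherwise the eudicot or monocot panel by which clade holds
    all angiosperm carriers.  Opposite-strand pairs go to their own panel
    regardless of depth.
    """
    basal, outgroup = anchors
    assignments = {}
    for label in grid.presence.index:
        pair = grid.pairs[label]
        carriers = grid.carriers(label)
        if pair.orientation == OPPOSITE:
            assignments[label] = OPPOSITE_PANEL
            continue
        mono = any(groups.is_monocot(sp) for sp in carriers)
        eudi = any(groups.is_eudicot(sp) for sp in carriers)
        magn = any(groups[sp] == "magnoliid" for sp in carriers)
        outg = any(groups[sp] == "gymnosperm_outgroup" for sp in carriers)
        clades = sum([magn, mono, eudi])
        if clades >= 2 or (outg and (magn or mono or eudi)):
            assignments[label] = ANCESTRAL
        elif eudi:
            assignments[label] = EUDICOT_PANEL
        elif mono:
            assignments[label] = MONOCOT_PANEL
        else:
            assignments[label] = UNREPORTED
    out = PresenceGrid(grid.presence, grid.pairs)
    out.assignment = pd.Series(assignments, index=grid.presence.index, dtype=object)
    return out
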