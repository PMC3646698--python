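"""C-to-U RNA editing site calling and edit-matrix construction.

Editing sites are detected as genomic C vs cDNA T mismatches between in-frame
CDS pairs.  Sites across taxa are collected into a presence/absence matrix
('0' = covered but unedited, '1' = edited, '?' = missing data due to gene loss
or lack of cDNA), and each site is classified as synonymous or nonsynonymous
by translating the reference taxon's codon with and without the single C→T
change under the standard genetic code (plant mitochondria use the standard
code).  Sites in codons carrying multiple edits, or where the reference taxon
does not encode a C, are excluded from the partitioned counts but kept in the
matrix totals.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

STANDARD_CODE = CodonTable.unambiguous_dna_by_id[1]

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
EXCLUDED = "excluded"

EXCL_NONE = "none"
EXCL_MULTI = "multi_edit_codon"
EXCL_REF_NOT_C = "ref_not_C"


class EditCallError(ValueError):
    pass


@dataclass(frozen=True)
class EditSite:
    """One C-to-U editing site in one taxon's gene."""

    gene: str
    column: int  # 1-based position in the in-frame CDS
    codon_index: int  # 1-based codon number
    codon_pos: int  # 1, 2 or 3
    genomic_base: str = "C"
    edited_base: str = "T"
    codon: str = "???"  # the genomic codon containing the site

    def __post_init__(self) -> None:
        if self.genomic_base != "C":
            raise EditCallError("editing sites must have genomic base C")
        if self.codon_pos != ((self.column - 1) % 3) + 1:
            raise EditCallError("codon_pos inconsistent with column")


@dataclass(frozen=True)
class Mismatch:
    """A non-C-to-T difference between genomic and cDNA sequence (QC output)."""

    gene: str
    column: int
    genomic_base: str
    cdna_base: str


def call_edit_sites(
    genomic_cds: str, cdna_cds: str, gene: str
) -> tuple[list[EditSite], list[Mismatch]]:
    """Compare an in-frame genomic CDS with its cDNA.

    Every genomic-C / cDNA-T position becomes an :class:`EditSite`; any other
    mismatch is returned as QC output, never silently dropped.  Positions where
    either sequence is N are skipped with a warning.
    """
    g = genomic_cds.upper()
    c = cdna_cds.upper()
    if len(g) != len(c):
        raise EditCallError(f"{gene}: length mismatch {len(g)} vs {len(c)}")
    if len(g) % 3 != 0:
        raise EditCallError(f"{gene}: length {len(g)} not divisible by 3")
    if "-" in g or "-" in c:
        raise EditCallError(f"{gene}: gaps not allowed in CDS pairs")
    bad = set(g + c) - set("ACGTN")
    if bad:
        raise EditCallError(f"{gene}: ambiguity codes {sorted(bad)} not supported")

    sites: list[EditSite] = []
    others: list[Mismatch] = []
    for i, (gb, cb) in enumerate(zip(g, c)):
        if gb == cb:
            continue
        if "N" in (gb, cb):
            warnings.warn(f"{gene}: N at column {i + 1} skipped", stacklevel=2)
            continue
        codon_index = i // 3 + 1
        if gb == "C" and cb == "T":
            codon = g[(codon_index - 1) * 3 : codon_index * 3]
            sites.append(
                EditSite(gene, i + 1, codon_index, i % 3 + 1, codon=codon)
            )
        else:
            others.append(Mismatch(gene, i + 1, gb, cb))
    return sites, others


def apply_edits(genomic_cds: str, sites: list[EditSite]) -> str:
    """Apply C→T edits to a genomic CDS (inverse of :func:`call_edit_sites`)."""
    seq = list(genomic_cds.upper())
    for s in sites:
        if seq[s.column - 1] != "C":
            raise EditCallError(f"{s.gene}:{s.column} is not C")
        seq[s.column - 1] = "T"
    return "".join(seq)


def classify_edit_effect(reference_codon: str, codon_position: int) -> str:
    """Synonymous or nonsynonymous effect of a single C→U edit.

    Translates the reference codon and the codon with C→T applied at
    ``codon_position`` (1-based) under the standard genetic code.
    """
    codon = reference_codon.upper()
    if len(codon) != 3 or set(codon) - set("ACGT"):
        raise EditCallError(f"bad codon {reference_codon!r}")
    if codon_position not in (1, 2, 3):
        raise EditCallError(f"bad codon position {codon_position}")
    if codon[codon_position - 1] != "C":
        raise EditCallError(f"codon {codon} lacks C at position {codon_position}")
    edited = codon[: codon_position - 1] + "T" + codon[codon_position:]
    before = str(Seq(codon).translate(table=STANDARD_CODE))
    after = str(Seq(edited).translate(table=STANDARD_CODE))
    return SYNONYMOUS if before == after else NONSYNONYMOUS


@dataclass
class EditMatrix:
    """Taxa x sites presence/absence matrix of editing with site metadata.

    ``cells``: DataFrame indexed by site_id, one column per taxon, values in
    {'0','1','?'}.  ``sites``: per-site metadata (gene, column, codon_index,
    codon_pos, ref_codon, effect, excl_reason).
    """

    cells: pd.DataFrame
    sites: pd.DataFrame
    reference_taxon: str | None = None
    dropped_all_zero: int = 0

    @property
    def taxa(self) -> list[str]:
        return list(self.cells.columns)

    def n_sites(self) -> int:
        return len(self.cells)

    def edited_counts(self) -> pd.Series:
        """Number of edited sites per taxon."""
        return (self.cells == "1").sum(axis=0)

    def site_ids(self, partition: str = "all") -> list[str]:
        """Site ids for a partition: 'all', 'synonymous' or 'nonsynonymous'."""
        if partition == "all":
            return list(self.sites.index)
        if partition in (SYNONYMOUS, NONSYNONYMOUS):
            keep = self.sites["effect"] == partition
            return list(self.sites.index[keep])
        raise ValueError(f"unknown partition {partition!r}")

    def column(self, site_id: str) -> dict[str, str]:
        return self.cells.loc[site_id].to_dict()


SITE_FIELDS = ["gene", "column", "codon_index", "codon_pos", "ref_codon", "effect", "excl_reason"]


def build_edit_matrix(
    per_taxon_sites: dict[str, list[EditSite]],
    coverage: dict[str, set[tuple[str, int]]],
    reference_taxon: str,
    reference_seqs: dict[str, str] | None = None,
) -> EditMatrix:
    """Assemble the multi-taxon 0/1/? matrix from per-taxon edit-site calls.

    ``coverage`` maps each taxon to the set of (gene, column) positions with
    sequence data; sites outside a taxon's coverage are '?'.  The site list is
    the union of edited positions across taxa (every retained site has at
    least one '1').  Reference codon context comes from the reference taxon's
    own edit call where it edits, else from ``reference_seqs`` (gene -> genomic
    CDS) where covered, else '?'.
    """
    if reference_taxon not in per_taxon_sites:
        raise EditCallError(f"reference taxon {reference_taxon!r} absent from input")
    for taxon, sites in per_taxon_sites.items():
        cov = coverage.get(taxon, set())
        for s in sites:
            if (s.gene, s.column) not in cov:
                raise EditCallError(
                    f"{taxon}: edit at {s.gene}:{s.column} outside declared coverage"
                )

    by_pos: dict[tuple[str, int], dict[str, EditSite]] = {}
    for taxon, sites in per_taxon_sites.items():
        for s in sites:
            by_pos.setdefault((s.gene, s.column), {})[taxon] = s

    taxa = sorted(per_taxon_sites)
    positions = sorted(by_pos)
    rows, meta = [], []
    index = []
    for gene, column in positions:
        editors = by_pos[(gene, column)]
        cells = {}
        for taxon in taxa:
            if taxon in editors:
                cells[taxon] = "1"
            elif (gene, column) in coverage.get(taxon, set()):
                cells[taxon] = "0"
            else:
                cells[taxon] = "?"
        any_site = next(iter(editors.values()))
        if reference_taxon in editors:
            ref_codon = editors[reference_taxon].codon
        elif (gene, column) in coverage.get(reference_taxon, set()) and reference_seqs and gene in reference_seqs:
            ci = any_site.codon_index
            ref_codon = reference_seqs[gene].upper()[(ci - 1) * 3 : ci * 3]
        else:
            ref_codon = "?"
        rows.append(cells)
        meta.append(
            {
                "gene": gene,
                "column": column,
                "codon_index": any_site.codon_index,
                "codon_pos": any_site.codon_pos,
                "ref_codon": ref_codon,
                "effect": EXCLUDED,
                "excl_reason": EXCL_NONE,
            }
        )
        index.append(f"{gene}.{column}")
    cells_df = pd.DataFrame(rows, index=index, columns=taxa, dtype=str)
    sites_df = pd.DataFrame(meta, index=index, columns=SITE_FIELDS)
    return EditMatrix(cells_df, sites_df, reference_taxon)


def apply_partition_filter(matrix: EditMatrix) -> EditMatrix:
    """Label sites synonymous/nonsynonymous and set exclusion reasons.

    Sites sharing a codon with another edited site are excluded
    (multi_edit_codon); sites where the reference taxon's genomic base is not
    a C (G/A encoded, or no reference context) are excluded (ref_not_C).
    Excluded sites remain in the matrix for total counts, so the partitioned
    counts sum to less than the total.
    """
    sites = matrix.sites.copy()
    codon_counts = sites.groupby(["gene", "codon_index"]).size()
    effects, reasons = [], []
    for _, row in sites.iterrows():
        if codon_counts[(row["gene"], row["codon_index"])] > 1:
            effects.append(EXCLUDED)
            reasons.append(EXCL_MULTI)
            continue
        codon = row["ref_codon"]
        pos = row["codon_pos"]
        if len(codon) != 3 or codon[pos - 1] != "C":
            effects.append(EXCLUDED)
            reasons.append(EXCL_REF_NOT_C)
            continue
        effects.append(classify_edit_effect(codon, pos))
        reasons.append(EXCL_NONE)
    sites["effect"] = effects
    sites["excl_reason"] = reasons
    return EditMatrix(
        matrix.cells, sites, matrix.reference_taxon, matrix.dropped_all_zero
    )


# ---------------------------------------------------------------------------
# TSV round-trip


def write_edit_matrix(matrix: EditMatrix) -> str:
    buf = io.StringIO()
    taxa = matrix.taxa
    buf.write("site_id\t" + "\t".join(SITE_FIELDS) + "\t" + "\t".join(taxa) + "\n")
    for site_id in matrix.sites.index:
        meta = matrix.sites.loc[site_id]
        cells = matrix.cells.loc[site_id]
        buf.write(
            site_id
            + "\t"
            + "\t".join(str(meta[f]) for f in SITE_FIELDS)
            + "\t"
            + "\t".join(cells[t] for t in taxa)
            + "\n"
        )
    return buf.getvalue()


def parse_edit_matrix(tsv_text: str, reference_taxon: str | None = None) -> EditMatrix:
    lines = [ln for ln in tsv_text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header[: 1 + len(SITE_FIELDS)] != ["site_id"] + SITE_FIELDS:
        raise EditCallError("bad edit-matrix header")
    taxa = header[1 + len(SITE_FIELDS) :]
    meta_rows, cell_rows, index = [], [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        site_id = parts[0]
        meta = dict(zip(SITE_FIELDS, parts[1 : 1 + len(SITE_FIELDS)]))
        for key in ("column", "codon_index", "codon_pos"):
            meta[key] = int(meta[key])
        states = parts[1 + len(SITE_FIELDS) :]
        bad = set(states) - {"0", "1", "?"}
        if bad:
            raise EditCallError(f"{site_id}: bad cell values {bad}")
        index.append(site_id)
        meta_rows.append(meta)
        cell_rows.append(dict(zip(taxa, states)))
    cells = pd.DataFrame(cell_rows, index=index, columns=taxa, dtype=str)
    sites = pd.DataFrame(meta_rows, index=index, columns=SITE_FIELDS)
    return EditMatrix(cells, sites, reference_taxon)
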