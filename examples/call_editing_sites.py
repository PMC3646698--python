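"""Call C-to-U editing sites from a genomic/cDNA CDS pair and classify them.

Every genomic-C / cDNA-T mismatch is an editing site; applying the edit to
the reference codon and translating tells whether the edit changes the
protein (nonsynonymous) or not.
"""

from mitofossil.edit_calling import (
    apply_partition_filter,
    build_edit_matrix,
    call_edit_sites,
    classify_edit_effect,
)

genomic = "ATGCCGTCACGGCTT"  # Met-Pro-Ser-Arg-Leu as encoded
cdna = "ATGTCGTTACGGCTT"  # two positions edited in the transcript

sites, other = call_edit_sites(genomic, cdna, gene="nad3")
print(f"{len(sites)} editing sites, {len(other)} non-canonical mismatches")
for s in sites:
    effect = classify_edit_effect(s.codon, s.codon_pos)
    print(f"  column {s.column:2d} codon {s.codon} position {s.codon_pos}: {effect}")

# assemble a two-taxon presence/absence matrix; taxon B lacks cDNA for the
# second codon region, so its cells there become '?' (missing data)
coverage = {
    "Liriodendron": {("nad3", s.column) for s in sites},
    "Nicotiana": {("nad3", 4)},
}
per_taxon = {"Liriodendron": sites, "Nicotiana": [sites[0]]}
matrix = apply_partition_filter(
    build_edit_matrix(per_taxon, coverage, "Liriodendron")
)
print("\nedit matrix (rows = sites, columns = taxa):")
print(matrix.cells)
print("\nsite effects:")
print(matrix.sites[["ref_codon", "codon_pos", "effect"]])
# A '1' means the taxon edits that site, '0' covered-but-unedited, '?' no data.
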