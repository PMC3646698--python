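"""Genome-content accounting under iterative category masking.

Given an ordered list of annotation categories (protein genes, cis-spliced
introns, rDNA, tRNA, plastid-like sequence, large repeats, shared intergenic,
small repeats, transposon-like, …), each with a set of 1-based inclusive
intervals, the tally reports per category both the *raw* coverage (union of
its own intervals, overlaps with earlier categories allowed) and the
*exclusive* coverage (after masking everything already claimed by earlier
categories).  Whatever is claimed by no category is the unknown-intergenic
remainder, so the exclusive amounts plus the remainder partition the genome
exactly, while the raw sum can exceed the genome size by the double-counted
overlap.  Intervals on circular genomes may wrap (start > end runs through
the origin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

Interval = tuple[int, int]


class IntervalError(ValueError):
    pass


@dataclass
class MaskCategoryReport:
    """Raw and exclusive bp per category plus the unknown remainder."""

    genome_length: int
    table: pd.DataFrame  # category, raw_bp, exclusive_bp (ordered)
    unknown_intergenic: int

    @property
    def raw_total(self) -> int:
        return int(self.table["raw_bp"].sum())

    @property
    def exclusive_total(self) -> int:
        return int(self.table["exclusive_bp"].sum())

    @property
    def overlap_excess(self) -> int:
        """bp double-counted across categories (raw sum minus exclusive sum)."""
        return self.raw_total - self.exclusive_total

    def to_tsv(self) -> str:
        df = self.table.copy()
        tail = pd.DataFrame(
            [
                {
                    "category": "unknown_intergenic",
                    "raw_bp": self.unknown_intergenic,
                    "exclusive_bp": self.unknown_intergenic,
                }
            ]
        )
        return pd.concat([df, tail], ignore_index=True).to_csv(sep="\t", index=False)


def _coverage_mask(
    genome_length: int, intervals: list[Interval], name: str
) -> np.ndarray:
    mask = np.zeros(genome_length, dtype=bool)
    for start, end in intervals:
        if not (1 <= start <= genome_length and 1 <= end <= genome_length):
            raise IntervalError(
                f"{name}: interval {start}..{end} outside [1, {genome_length}]"
            )
        if start <= end:
            mask[start - 1 : end] = True
        else:  # wraps through the origin of a circular genome
            mask[start - 1 :] = True
            mask[:end] = True
    return mask


def tally_categories(
    genome_length: int, categories: list[tuple[str, list[Interval]]]
) -> MaskCategoryReport:
    """Tally raw and exclusive coverage per category in the given order."""
    if genome_length < 1:
        raise IntervalError("genome length must be positive")
    claimed = np.zeros(genome_length, dtype=bool)
    rows = []
    for name, intervals in categories:
        own = _coverage_mask(genome_length, intervals, name)
        raw = int(own.sum())
        exclusive = int((own & ~claimed).sum())
        claimed |= own
        rows.append({"category": name, "raw_bp": raw, "exclusive_bp": exclusive})
    unknown = int(genome_length - claimed.sum())
    table = pd.DataFrame(rows, columns=["category", "raw_bp", "exclusive_bp"])
    return MaskCategoryReport(genome_length, table, unknown)
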