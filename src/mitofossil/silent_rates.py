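"""Silent (synonymous) substitution estimation and absolute-rate scaling.

Pairwise synonymous divergence is computed by Nei–Gojobori (1986) counting:
per-codon synonymous site fractions averaged over the two sequences, with
multi-difference codons averaged over all minimal mutational paths (paths
through stop codons excluded when possible), followed by the Jukes–Cantor
correction dS = −(3/4)·ln(1 − (4/3)·pS).  Branch-specific silent substitution
amounts on a fixed rooted topology are obtained by non-negative least squares
on path sums of the pairwise dS matrix (exact on additive matrices), and are
converted to absolute rates in silent substitutions per site per billion
years (ssb) by dividing each branch amount by its duration on a dated
chronogram.

Note on identifiability: for a rooted binary tree, pairwise distances
determine only the *sum* of the two root-adjacent branches.  The fit
estimates that merged edge and splits it between the two branches in
proportion to their durations when the topology carries branch lengths
(equally otherwise).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import linregress

from .core_io import DatedTree, MY
from .edit_calling import EditMatrix, STANDARD_CODE

BASES = "TCAG"
CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
STOPS = set(STANDARD_CODE.stop_codons)


def _aa(codon: str) -> str:
    return "*" if codon in STOPS else STANDARD_CODE.forward_table[codon]


def _syn_fraction(codon: str) -> float:
    """NG86 synonymous site count of a codon (sum over 3 positions of the
    fraction of the three possible changes that are synonymous; changes to
    stop codons count as nonsynonymous)."""
    if codon in STOPS:
        return 0.0
    total = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOPS and _aa(alt) == _aa(codon):
                syn += 1
        total += syn / 3.0
    return total


def _path_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences between two codons over
    all minimal mutational paths, excluding paths through *intermediate* stop
    codons when any stop-free path exists (endpoint stops do not disqualify a
    path; they are normally masked before counting)."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        cur = c1
        syn = nsyn = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS and nxt != c2:
                through_stop = True
            if cur not in STOPS and nxt not in STOPS and _aa(cur) == _aa(nxt):
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        paths.append((through_stop, syn, nsyn))
    clean = [p for p in paths if not p[0]]
    use = clean if clean else paths
    syn = sum(p[1] for p in use) / len(use)
    nsyn = sum(p[2] for p in use) / len(use)
    return syn, nsyn


# precomputed lookup tables over all 64 codons / 64x64 codon pairs
SYN_SITES = np.array([_syn_fraction(c) for c in CODONS])
_SD = np.zeros((64, 64))
for _i, _c1 in enumerate(CODONS):
    for _j, _c2 in enumerate(CODONS):
        if _j > _i:
            continue
        _s, _ = _path_diffs(_c1, _c2)
        _SD[_i, _j] = _SD[_j, _i] = _s


class RateError(ValueError):
    pass


class SaturationError(RateError):
    pass


def encode_codons(seq: str) -> np.ndarray:
    """Codon-index array for an in-frame, gap-free DNA string."""
    s = seq.upper()
    if len(s) % 3 != 0:
        raise RateError(f"length {len(s)} not divisible by 3")
    try:
        return np.array([CODON_INDEX[s[i : i + 3]] for i in range(0, len(s), 3)])
    except KeyError as exc:
        raise RateError(f"non-ACGT codon {exc}") from exc


def jc_correct(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 0.75; correction undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def pairwise_ds(seq_a: str, seq_b: str) -> float:
    """NG86 synonymous divergence with Jukes–Cantor correction."""
    a, b = encode_codons(seq_a), encode_codons(seq_b)
    if len(a) != len(b):
        raise RateError("sequence lengths differ")
    s_sites = 0.5 * (SYN_SITES[a].sum() + SYN_SITES[b].sum())
    if s_sites <= 0:
        raise RateError("zero synonymous sites")
    s_diffs = _SD[a, b].sum()
    return jc_correct(s_diffs / s_sites)


# ---------------------------------------------------------------------------
# Codon alignment container and masking

MASK_EDITED = "edited"
MASK_STOP = "stop"
MASK_LOW_QUALITY = "low_quality"


@dataclass
class CodonAlignment:
    """In-frame multiple alignment with per-codon mask flags."""

    taxa: list[str]
    seqs: dict[str, str]
    mask: dict[int, str] = field(default_factory=dict)  # codon index (0-based) -> reason

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) != 1:
            raise RateError("aligned sequences differ in length")
        (self.length,) = lengths
        if self.length % 3 != 0:
            raise RateError("alignment length not divisible by 3")
        for taxon, s in self.seqs.items():
            for i in range(0, len(s), 3):
                codon = s[i : i + 3]
                if "-" in codon and codon != "---":
                    raise RateError(f"{taxon}: gap not aligned in codon triplet at {i + 1}")

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def unmasked_pair(self, taxon_a: str, taxon_b: str) -> tuple[str, str]:
        """Gap-free, unmasked codon strings for a pair of taxa."""
        sa, sb = self.seqs[taxon_a].upper(), self.seqs[taxon_b].upper()
        keep_a, keep_b = [], []
        for k in range(self.n_codons):
            if k in self.mask:
                continue
            ca, cb = sa[3 * k : 3 * k + 3], sb[3 * k : 3 * k + 3]
            if "-" in ca or "-" in cb:
                continue
            keep_a.append(ca)
            keep_b.append(cb)
        return "".join(keep_a), "".join(keep_b)


def mask_alignment(
    aln: CodonAlignment,
    matrix: EditMatrix | None = None,
    quality_mask: list[tuple[int, int]] | None = None,
) -> CodonAlignment:
    """Mask codon columns edited in any taxon, stop codons in any taxon, and
    supplied low-quality codon intervals (1-based codon indices, inclusive)."""
    mask = dict(aln.mask)
    if matrix is not None:
        for _, row in matrix.sites.iterrows():
            k = (row["column"] - 1) // 3
            if k >= aln.n_codons:
                raise RateError(
                    f"edit matrix column {row['column']} beyond alignment"
                )
            mask.setdefault(k, MASK_EDITED)
    for taxon in aln.taxa:
        s = aln.seqs[taxon].upper()
        for k in range(aln.n_codons):
            if s[3 * k : 3 * k + 3] in STOPS:
                mask.setdefault(k, MASK_STOP)
    for start, end in quality_mask or []:
        for k in range(start - 1, end):
            mask.setdefault(k, MASK_LOW_QUALITY)
    return CodonAlignment(aln.taxa, aln.seqs, mask)


def ds_matrix(aln: CodonAlignment) -> pd.DataFrame:
    """Symmetric pairwise dS table over all taxa of an alignment."""
    taxa = aln.taxa
    out = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for a, b in itertools.combinations(taxa, 2):
        sa, sb = aln.unmasked_pair(a, b)
        d = pairwise_ds(sa, sb)
        out.loc[a, b] = out.loc[b, a] = d
    return out


# ---------------------------------------------------------------------------
# Branch fitting and absolute rates


def _fit_edges(tree: DatedTree) -> tuple[list[tuple[int, ...]], dict[int, int]]:
    """Identifiable edges: each a tuple of branch ids; the two root-adjacent
    branches of a bifurcating root merge into one edge."""
    root_children = tree.nodes[tree.root].children
    merged: tuple[int, ...] | None = None
    edges: list[tuple[int, ...]] = []
    if len(root_children) == 2:
        merged = tuple(root_children)
        edges.append(merged)
        rest = [v for v in tree.branch_ids() if v not in root_children]
    else:
        rest = list(tree.branch_ids())
    edges.extend((v,) for v in rest)
    branch_to_edge = {}
    for ei, edge in enumerate(edges):
        for v in edge:
            branch_to_edge[v] = ei
    return edges, branch_to_edge


def fit_branch_rates(topology: DatedTree, ds: pd.DataFrame) -> dict[int, float]:
    """Non-negative least-squares fit of per-branch subs/site to pairwise dS.

    Returns subs/site per branch id.  Exact on additive matrices.  The merged
    root edge is split between the two root-adjacent branches in proportion
    to the topology's branch lengths when present, else equally.
    """
    leaves = {topology.nodes[v].label: v for v in topology.leaves}
    missing = set(ds.index) - set(leaves)
    if missing:
        raise RateError(f"taxa not on tree: {sorted(missing)}")
    edges, branch_to_edge = _fit_edges(topology)
    pairs = list(itertools.combinations(ds.index, 2))
    A = np.zeros((len(pairs), len(edges)))
    d = np.zeros(len(pairs))
    for r, (ta, tb) in enumerate(pairs):
        for v in topology.path_branches(leaves[ta], leaves[tb]):
            A[r, branch_to_edge[v]] = 1.0
        d[r] = ds.loc[ta, tb]
    x, _ = nnls(A, d)
    out: dict[int, float] = {}
    for ei, edge in enumerate(edges):
        if len(edge) == 1:
            out[edge[0]] = float(x[ei])
        else:
            a, b = edge
            la = topology.nodes[a].length
            lb = topology.nodes[b].length
            if la is None or lb is None or la + lb == 0:
                wa = 0.5
            else:
                wa = la / (la + lb)
            out[a] = float(x[ei]) * wa
            out[b] = float(x[ei]) * (1 - wa)
    return out


@dataclass
class BranchRateTable:
    """Per-branch silent substitutions, durations, and absolute rates (ssb)."""

    table: pd.DataFrame  # branch_id, label, clade, subs, duration_my, ssb

    def terminal_rates(self) -> pd.Series:
        term = self.table[self.table["label"] != ""]
        return pd.Series(term["ssb"].values, index=term["label"].values)

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False)


def absolute_rates(
    branch_subs: dict[int, float], chronogram: DatedTree
) -> BranchRateTable:
    """Scale per-branch subs/site to ssb = subs ÷ (duration in billion years).

    ``branch_subs`` is keyed by branch id on the *chronogram's* topology (use
    :func:`transfer_branch_values` if the fit was done on a different tree
    object with the same shape).
    """
    if chronogram.units != MY:
        raise RateError("chronogram must carry durations in million years")
    rows = []
    for v in chronogram.branch_ids():
        subs = branch_subs.get(v, 0.0)
        dur = chronogram.nodes[v].length or 0.0
        if dur == 0.0:
            if subs > 0:
                raise RateError(f"branch {v}: nonzero subs on zero-duration branch")
            ssb = 0.0
        else:
            ssb = subs / (dur / 1000.0)
        rows.append(
            {
                "branch_id": v,
                "label": chronogram.nodes[v].label or "",
                "subs": subs,
                "duration_my": dur,
                "ssb": ssb,
            }
        )
    return BranchRateTable(pd.DataFrame(rows))


def transfer_branch_values(
    source: DatedTree, target: DatedTree, values: dict[int, float]
) -> dict[int, float]:
    """Re-key per-branch values from one tree to a topologically identical one
    by matching the leaf-label set below each branch."""
    by_clade = {source.clade_key(v): x for v, x in values.items()}
    out = {}
    for v in target.branch_ids():
        key = target.clade_key(v)
        if key not in by_clade:
            raise RateError(f"clade {sorted(key)} absent from source tree")
        out[v] = by_clade[key]
    return out


# ---------------------------------------------------------------------------
# Cross-genome comparisons


@dataclass
class RateRatioStats:
    slope: float
    intercept: float
    r_squared: float
    mean_ratio: float
    sd_ratio: float
    ratios: pd.Series


def rate_ratio_stats(
    cp_rates: pd.Series,
    mt_rates: pd.Series,
    omit: set[str] | frozenset[str] = frozenset(),
) -> RateRatioStats:
    """Chloroplast-vs-mitochondrial rate comparison across taxa.

    Ordinary least squares of cp on mt (free intercept) plus the mean and
    sample standard deviation of per-taxon cp/mt ratios, after dropping the
    taxa in ``omit`` (e.g. superfast mitochondrial lineages).
    """
    taxa = [t for t in cp_rates.index if t in mt_rates.index and t not in omit]
    if len(taxa) < 3:
        raise RateError("fewer than 3 paired taxa after omission")
    cp = cp_rates[taxa].astype(float)
    mt = mt_rates[taxa].astype(float)
    if (mt == 0).any():
        raise RateError("zero mitochondrial rate; ratio undefined")
    fit = linregress(mt.values, cp.values)
    ratios = cp / mt
    return RateRatioStats(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        mean_ratio=float(ratios.mean()),
        sd_ratio=float(ratios.std(ddof=1)),
        ratios=ratios,
    )


def divergence_time_equivalent(
    rate_ref: float, rate_target: float, years_ref: float
) -> float:
    """Years needed in the target lineage to accrue the silent divergence the
    reference lineage accrues in ``years_ref`` years."""
    if rate_ref <= 0 or rate_target <= 0:
        raise RateError("rates must be positive")
    return years_ref * rate_ref / rate_target
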