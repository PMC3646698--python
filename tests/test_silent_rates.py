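import itertools
import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from mitofossil.core_io import parse_dated_tree
from mitofossil.edit_calling import apply_partition_filter, build_edit_matrix
from mitofossil.silent_rates import (
    CodonAlignment,
    MASK_EDITED,
    MASK_STOP,
    RateError,
    RateRatioStats,
    SaturationError,
    absolute_rates,
    divergence_time_equivalent,
    ds_matrix,
    fit_branch_rates,
    mask_alignment,
    pairwise_ds,
    rate_ratio_stats,
    transfer_branch_values,
)
from tests.test_edit_calling import call_edit_sites_codon


class TestPairwiseDs:
    def test_identical_sequences_have_zero_ds(self):
        assert pairwise_ds("ATGCCGTTT", "ATGCCGTTT") == 0.0

    def test_hand_ng86_example(self):
        # 10 Phe codons, one synonymous third-position difference:
        # S = 10/3 per sequence, Sd = 1, pS = 0.3, dS = -0.75 ln(0.6)
        ds = pairwise_ds("TTT" * 10, "TTT" * 9 + "TTC")
        assert ds == pytest.approx(-0.75 * math.log(0.6), rel=1e-12)

    def test_purely_nonsynonymous_difference_gives_zero(self):
        assert pairwise_ds("ATG" * 5, "GTG" * 5) == 0.0

    def test_symmetry_and_monotonicity(self):
        base = ["GGT"] * 30
        prev = 0.0
        for k in (1, 3, 6):
            other = ["GGA"] * k + ["GGT"] * (30 - k)
            d_ab = pairwise_ds("".join(base), "".join(other))
            d_ba = pairwise_ds("".join(other), "".join(base))
            assert d_ab == d_ba
            assert d_ab > prev
            prev = d_ab

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            pairwise_ds("GGT" * 4, "GGA" * 4)  # every syn site differs

    def test_zero_synonymous_sites_rejected(self):
        with pytest.raises(RateError, match="zero synonymous"):
            pairwise_ds("ATG", "ATG")  # Met has no synonymous changes

    def test_length_mismatch_rejected(self):
        with pytest.raises(RateError):
            pairwise_ds("ATGATG", "ATG")


class TestNG86AgainstPathOracle:
    """Independent re-derivation of per-codon site counts and path-averaged
    differences for codon pairs, written from first principles."""

    @staticmethod
    def _aa(codon):
        return str(Seq(codon).translate())

    def test_syn_site_counts_for_sample_codons(self):
        from mitofossil.silent_rates import CODON_INDEX, SYN_SITES

        for codon in ("TTT", "GGG", "ATG", "TGG", "CTA", "AGA"):
            expected = 0.0
            for pos in range(3):
                syn = 0
                for b in "TCAG":
                    if b == codon[pos]:
                        continue
                    alt = codon[:pos] + b + codon[pos + 1 :]
                    if self._aa(alt) != "*" and self._aa(alt) == self._aa(codon):
                        syn += 1
                expected += syn / 3
            assert SYN_SITES[CODON_INDEX[codon]] == pytest.approx(expected)

    def test_two_difference_codon_path_average(self):
        # TTT -> GTC: paths TTT->GTT->GTC (nonsyn, syn) and
        # TTT->TTC->GTC (syn, nonsyn); average 1 syn, 1 nonsyn
        from mitofossil.silent_rates import CODON_INDEX, _SD

        assert _SD[CODON_INDEX["TTT"], CODON_INDEX["GTC"]] == pytest.approx(1.0)


def _aln(seqs):
    return CodonAlignment(sorted(seqs), seqs)


class TestMaskAlignment:
    def test_edit_in_any_taxon_masks_codon_for_all(self):
        aln = _aln({"A": "ATGCCGGGG", "B": "ATGCCGGGG"})
        cov = {"A": {("g", 4)}}
        sites = {"A": [call_edit_sites_codon("g", 4, 1, "CCG")]}
        matrix = apply_partition_filter(build_edit_matrix(sites, cov, "A"))
        masked = mask_alignment(aln, matrix)
        assert masked.mask == {1: MASK_EDITED}
        a, b = masked.unmasked_pair("A", "B")
        assert len(a) == 6  # codon 2 dropped for the pair

    def test_stop_codon_in_one_taxon_masks_column(self):
        aln = _aln({"A": "ATGTAAGGG", "B": "ATGCAAGGG"})
        masked = mask_alignment(aln)
        assert masked.mask == {1: MASK_STOP}

    def test_clean_alignment_unchanged(self):
        aln = _aln({"A": "ATGCCG", "B": "ATGCCG"})
        assert mask_alignment(aln).mask == {}

    def test_quality_intervals_masked(self):
        aln = _aln({"A": "ATGCCGGGG", "B": "ATGCCGGGG"})
        masked = mask_alignment(aln, quality_mask=[(2, 3)])
        assert set(masked.mask) == {1, 2}

    def test_gap_codons_dropped_pairwise(self):
        aln = _aln({"A": "ATG---GGT", "B": "ATGCCGGGA"})
        a, b = aln.unmasked_pair("A", "B")
        assert (a, b) == ("ATGGGT", "ATGGGA")

    def test_misaligned_gap_rejected(self):
        with pytest.raises(RateError, match="triplet"):
            _aln({"A": "ATG-CG", "B": "ATGCCG"})


class TestFitBranchRates:
    def test_additive_three_leaf_exact_recovery(self):
        tree = parse_dated_tree("(A:1,B:1,C:1);", units="subs")
        true = {tree.leaf_id(l): x for l, x in zip("ABC", (0.1, 0.2, 0.3))}
        ds = pd.DataFrame(0.0, index=list("ABC"), columns=list("ABC"))
        for x, y in itertools.combinations("ABC", 2):
            d = true[tree.leaf_id(x)] + true[tree.leaf_id(y)]
            ds.loc[x, y] = ds.loc[y, x] = d
        fit = fit_branch_rates(tree, ds)
        for v, x in true.items():
            assert fit[v] == pytest.approx(x, abs=1e-9)

    def test_nonnegativity_on_star_data(self):
        tree = parse_dated_tree("(A:1,B:1,C:1);", units="subs")
        ds = pd.DataFrame(
            [[0, 0.1, 0.1], [0.1, 0, 0.1], [0.1, 0.1, 0]],
            index=list("ABC"), columns=list("ABC"),
        )
        fit = fit_branch_rates(tree, ds)
        assert all(x >= 0 for x in fit.values())

    def test_additive_quartet_with_root_split_by_duration(self, quartet):
        # root-adjacent branches share one identifiable edge; equal durations
        # mean the merged amount splits evenly
        leaf = {l: quartet.leaf_id(l) for l in "ABCD"}
        internal = {quartet.nodes[leaf["A"]].parent, quartet.nodes[leaf["C"]].parent}
        true = {v: 0.05 for v in quartet.branch_ids()}
        ds = pd.DataFrame(0.0, index=list("ABCD"), columns=list("ABCD"))
        for x, y in itertools.combinations("ABCD", 2):
            d = sum(true[v] for v in quartet.path_branches(leaf[x], leaf[y]))
            ds.loc[x, y] = ds.loc[y, x] = d
        fit = fit_branch_rates(quartet, ds)
        for v in quartet.branch_ids():
            assert fit[v] == pytest.approx(0.05, abs=1e-9)

    def test_unknown_taxon_rejected(self, quartet):
        ds = pd.DataFrame(0.0, index=list("AXCD"), columns=list("AXCD"))
        with pytest.raises(RateError, match="not on tree"):
            fit_branch_rates(quartet, ds)


class TestAbsoluteRates:
    def test_liriodendron_magnitude_arithmetic(self):
        tree = parse_dated_tree("(A:100,B:100);")
        subs = {tree.leaf_id("A"): 0.0035, tree.leaf_id("B"): 0.0}
        table = absolute_rates(subs, tree)
        rates = table.terminal_rates()
        assert rates["A"] == pytest.approx(0.035)
        assert rates["B"] == 0.0

    def test_rate_times_duration_is_exactly_subs(self):
        tree = parse_dated_tree("((A:10,B:10):90,C:100);")
        subs = {v: 0.001 * (v + 1) for v in tree.branch_ids()}
        table = absolute_rates(subs, tree)
        for _, row in table.table.iterrows():
            assert row["ssb"] * row["duration_my"] / 1000 == pytest.approx(row["subs"])

    def test_zero_duration_with_subs_rejected(self):
        tree = parse_dated_tree("(A:0,B:100);")
        with pytest.raises(RateError, match="zero-duration"):
            absolute_rates({tree.leaf_id("A"): 0.05}, tree)

    def test_transfer_by_clade_between_tree_objects(self):
        t1 = parse_dated_tree("((A:1,B:1):1,C:2);")
        t2 = parse_dated_tree("(C:2,(B:1,A:1):1);")
        vals = {v: float(v) for v in t1.branch_ids()}
        moved = transfer_branch_values(t1, t2, vals)
        for v in t2.branch_ids():
            key = t2.clade_key(v)
            src = [b for b in t1.branch_ids() if t1.clade_key(b) == key][0]
            assert moved[v] == vals[src]


class TestRateRatioStats:
    def test_equal_rates_give_unit_slope_and_ratio(self):
        cp = pd.Series([0.5, 1.0, 2.0, 3.0], index=list("ABCD"))
        stats = rate_ratio_stats(cp, cp.copy())
        assert stats.slope == pytest.approx(1.0)
        assert stats.mean_ratio == pytest.approx(1.0)
        assert stats.sd_ratio == pytest.approx(0.0)

    def test_doubled_rates_give_slope_two_perfect_fit(self):
        mt = pd.Series([0.5, 1.0, 2.0, 3.0], index=list("ABCD"))
        stats = rate_ratio_stats(2 * mt, mt)
        assert stats.slope == pytest.approx(2.0)
        assert stats.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_ols(self):
        mt = pd.Series([0.1, 0.4, 0.9, 1.4, 3.0], index=list("ABCDE"))
        cp = pd.Series([0.5, 1.1, 1.6, 4.0, 6.5], index=list("ABCDE"))
        stats = rate_ratio_stats(cp, mt)
        slope, intercept = np.polyfit(mt.values, cp.values, 1)
        assert stats.slope == pytest.approx(slope)
        assert stats.intercept == pytest.approx(intercept)

    def test_omitted_superfast_taxa_dropped_before_fit(self):
        mt = pd.Series([0.1, 0.4, 0.9, 500.0], index=list("ABCD"))
        cp = pd.Series([0.2, 0.8, 1.8, 1.0], index=list("ABCD"))
        with_omit = rate_ratio_stats(cp, mt, omit={"D"})
        assert with_omit.slope == pytest.approx(2.0)
        assert "D" not in with_omit.ratios.index

    def test_too_few_pairs_rejected(self):
        s = pd.Series([1.0, 2.0], index=list("AB"))
        with pytest.raises(RateError, match="fewer than 3"):
            rate_ratio_stats(s, s.copy())


class TestDivergenceTimeEquivalent:
    def test_human_to_slow_lineage_scalings(self):
        assert divergence_time_equivalent(69.5, 0.035, 25) == pytest.approx(
            49642.857, rel=1e-6
        )
        assert divergence_time_equivalent(69.5, 0.013, 25) == pytest.approx(
            133653.846, rel=1e-6
        )

    def test_identity_when_rates_equal(self):
        assert divergence_time_equivalent(0.7, 0.7, 25) == 25

    def test_zero_rate_rejected(self):
        with pytest.raises(RateError):
            divergence_time_equivalent(69.5, 0.0, 25)


def test_ds_matrix_is_symmetric_zero_diagonal():
    seqs = {
        "A": "GGTGGAGGCCCT" * 10 + "GGT" * 24,
        "B": "GGAGGAGGCCCT" * 10 + "GGT" * 24,
        "C": "GGAGGTGGACCT" * 10 + "GGT" * 24,
    }
    aln = CodonAlignment(sorted(seqs), seqs)
    ds = ds_matrix(aln)
    assert np.allclose(ds.values, ds.values.T)
    assert np.all(np.diag(ds.values) == 0)
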