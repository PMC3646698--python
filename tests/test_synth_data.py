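import numpy as np
import pytest

from mitofossil.char_evolution import dollo_tally
from mitofossil.cluster_conservation import extract_clusters, species_pair_set, canonical_pair
from mitofossil.core_io import Gene, GeneOrderRecord
from mitofossil.insert_identity import fragment_identity_excluding_gaps, window_identity
from mitofossil.silent_rates import pairwise_ds
from mitofossil.synth_data import (
    simulate_codon_alignment,
    simulate_dated_tree,
    simulate_edit_matrix,
    simulate_gene_orders,
    simulate_plastid_insert,
)


class TestSimulateDatedTree:
    def test_two_taxa_cherry(self):
        tree = simulate_dated_tree(2, 100.0, 1)
        assert sorted(tree.leaf_labels) == ["T1", "T2"]
        assert all(tree.nodes[v].length == 100.0 for v in tree.leaves)

    def test_seed_determinism(self):
        assert (
            simulate_dated_tree(8, 200.0, 5).to_newick()
            == simulate_dated_tree(8, 200.0, 5).to_newick()
        )

    def test_shape_and_ultrametricity(self):
        tree = simulate_dated_tree(8, 200.0, 3)
        internal = [n for n in tree.nodes if n.children]
        assert len(internal) == 7
        assert tree.is_ultrametric()
        assert all(tree.nodes[v].length > 0 for v in tree.branch_ids())
        assert max(tree.depth(v) for v in tree.leaves) == pytest.approx(200.0)


class TestSimulateEditMatrix:
    def test_pure_loss_regime_is_dollo_consistent(self):
        tree = simulate_dated_tree(8, 200.0, 11)
        matrix, truth = simulate_edit_matrix(
            tree, n_ancestral_sites=150, gain_rate=0.0, seed=4
        )
        table = dollo_tally(tree, matrix)
        assert table.total_gains == matrix.n_sites()
        assert table.total_losses <= truth.records["true_losses_retained"]

    def test_no_loss_no_missing_is_all_ones(self):
        tree = simulate_dated_tree(6, 150.0, 2)
        matrix, _ = simulate_edit_matrix(
            tree, n_ancestral_sites=40, loss_rate=0.0, gain_rate=0.0,
            missing_frac=0.0, seed=9,
        )
        assert (matrix.cells.values == "1").all()
        assert dollo_tally(tree, matrix).total_losses == 0

    def test_determinism_and_truth_shape(self):
        tree = simulate_dated_tree(6, 150.0, 2)
        m1, t1 = simulate_edit_matrix(tree, 60, seed=7)
        m2, t2 = simulate_edit_matrix(tree, 60, seed=7)
        assert m1.cells.equals(m2.cells)
        assert t1.records == t2.records
        assert set(t1.records["sites"]) == set(m1.cells.index)

    def test_every_retained_site_observed_somewhere(self):
        tree = simulate_dated_tree(7, 180.0, 5)
        matrix, _ = simulate_edit_matrix(tree, 100, missing_frac=0.3, seed=3)
        assert ((matrix.cells == "1").sum(axis=1) >= 1).all()

    def test_clade_specific_loss_rates_spread_edit_totals(self):
        # fast-losing lineages end up with far fewer edited sites than the
        # slow, retentive lineage, spreading totals over a >2-fold range
        tree = simulate_dated_tree(10, 200.0, 21)
        slow = tree.leaf_id("T1")
        scale = {v: 4.0 for v in tree.branch_ids() if v != slow}
        matrix, _ = simulate_edit_matrix(
            tree, n_ancestral_sites=700, loss_rate=0.004, gain_rate=0.0005,
            missing_frac=0.05, seed=13, branch_loss_scale=scale,
        )
        counts = matrix.edited_counts()
        assert counts.max() / max(counts.min(), 1) > 2.0
        assert counts.idxmax() == "T1"


class TestSimulateCodonAlignment:
    def test_zero_divergence_gives_identical_sequences(self):
        tree = simulate_dated_tree(5, 100.0, 1)
        aln, _ = simulate_codon_alignment(
            tree, {v: 0.0 for v in tree.branch_ids()}, 200, seed=1
        )
        seqs = set(aln.seqs.values())
        assert len(seqs) == 1

    def test_cherry_pairwise_ds_near_sum_of_branches(self):
        tree = simulate_dated_tree(2, 100.0, 1)
        aln, _ = simulate_codon_alignment(
            tree, {v: 0.05 for v in tree.branch_ids()}, 5000, seed=8
        )
        d = pairwise_ds(aln.seqs["T1"], aln.seqs["T2"])
        # binomial sampling error on 5000 synonymous sites
        se = np.sqrt(0.1 * 0.9 / 5000)
        assert abs(d - 0.10) < 3 * se / (1 - 4 * 0.1 / 3)

    def test_determinism(self):
        tree = simulate_dated_tree(4, 100.0, 6)
        ds = {v: 0.02 for v in tree.branch_ids()}
        a1, _ = simulate_codon_alignment(tree, ds, 300, seed=5)
        a2, _ = simulate_codon_alignment(tree, ds, 300, seed=5)
        assert a1.seqs == a2.seqs

    def test_negative_ds_rejected(self):
        tree = simulate_dated_tree(3, 100.0, 2)
        with pytest.raises(ValueError, match="negative"):
            simulate_codon_alignment(tree, {1: -0.1}, 10, seed=0)


def _ancestor(n_genes=12, spacing=3000, length=None):
    genes = [
        Gene(f"g{i}", 1 + i * spacing, 1000 + i * spacing, "+") for i in range(n_genes)
    ]
    L = length or (n_genes * spacing + 2000)
    return GeneOrderRecord("anc", L, "circular", genes)


class TestSimulateGeneOrders:
    def test_zero_inversions_identity(self):
        anc = _ancestor()
        tree = simulate_dated_tree(5, 150.0, 3)
        recs, _ = simulate_gene_orders(anc, tree, 0.0, seed=1)
        for rec in recs.values():
            assert [g.name for g in rec.genes] == [g.name for g in anc.genes]

    def test_protected_adjacencies_survive(self):
        anc = _ancestor()
        tree = simulate_dated_tree(6, 150.0, 4)
        protected = [("g2", "g3"), ("g7", "g8")]
        recs, truth = simulate_gene_orders(anc, tree, 4.0, protected, seed=2)
        for sp, alive in truth.records["surviving_protected"].items():
            assert sorted(map(tuple, alive)) == [("g2", "g3"), ("g7", "g8")]
            pairs = species_pair_set(extract_clusters(recs[sp]))
            for a, b in protected:
                assert any(k.first == a and k.second == b for k in pairs)

    def test_more_inversions_break_more_ancestral_pairs(self):
        anc = _ancestor(n_genes=20)
        tree = simulate_dated_tree(6, 150.0, 9)
        ancestral_pairs = species_pair_set(extract_clusters(anc))

        def surviving(rate):
            recs, _ = simulate_gene_orders(anc, tree, rate, seed=5)
            kept = [
                len(ancestral_pairs & species_pair_set(extract_clusters(r)))
                for r in recs.values()
            ]
            return sum(kept)

        assert surviving(0.0) >= surviving(2.0) >= surviving(10.0)
        assert surviving(0.0) > surviving(10.0)

    def test_gene_lengths_and_genome_length_conserved(self):
        anc = _ancestor()
        tree = simulate_dated_tree(4, 100.0, 8)
        recs, _ = simulate_gene_orders(anc, tree, 3.0, seed=6)
        anc_lengths = sorted(g.end - g.start + 1 for g in anc.genes)
        for rec in recs.values():
            assert sorted(g.end - g.start + 1 for g in rec.genes) == anc_lengths
            assert rec.genome_length == anc.genome_length
            assert rec.genes[-1].end <= rec.genome_length

    def test_determinism(self):
        anc = _ancestor()
        tree = simulate_dated_tree(4, 100.0, 8)
        r1, t1 = simulate_gene_orders(anc, tree, 3.0, seed=6)
        r2, t2 = simulate_gene_orders(anc, tree, 3.0, seed=6)
        assert r1 == r2 and t1.records == t2.records


class TestSimulatePlastidInsert:
    def test_conserved_island_plateaus_at_hundred(self):
        pair, truth = simulate_plastid_insert(
            3500, (1500, 1580), 100.0, 84.0, seed=5
        )
        track = window_identity(*pair)
        inside = [
            ident
            for start, ident in zip(track.starts, track.identity)
            if start >= 1500 and start + 24 <= 1580
        ]
        assert inside and all(x == 100.0 for x in inside)

    def test_identical_flanks_give_flat_track(self):
        pair, _ = simulate_plastid_insert(500, (100, 200), 100.0, 100.0, seed=1)
        track = window_identity(*pair)
        assert all(x == 100.0 for x in track.identity)

    def test_fragment_identity_near_weighted_mean(self):
        L, isl = 4000, (1000, 2000)
        pair, _ = simulate_plastid_insert(L, isl, 100.0, 80.0, seed=3)
        island_cols = isl[1] - isl[0] + 1
        flank_cols = L - island_cols
        # per flank column: match 0.80, substitution 0.15, gap 0.05; the
        # gap-excluded identity weights columns by gap-free counts
        flank_gapfree = flank_cols * 0.95
        expected = 100 * (island_cols + flank_cols * 0.80) / (
            island_cols + flank_gapfree
        )
        got = fragment_identity_excluding_gaps(*pair)
        assert abs(got - expected) < 1.5

    def test_bad_island_rejected(self):
        with pytest.raises(ValueError, match="island"):
            simulate_plastid_insert(100, (50, 200), 100.0, 80.0, seed=0)
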