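"""Reconstruct gains and losses of editing sites under Dollo parsimony.

Simulates a chronogram and an edit matrix evolving under single-origin
dynamics (ancestral sites progressively lost, occasional new sites), then
tallies the most-parsimonious gain/loss events per branch.  Under Dollo each
site is gained exactly once; absences below the gain are explained by the
minimal set of losses.
"""

from mitofossil.char_evolution import dollo_tally
from mitofossil.synth_data import simulate_dated_tree, simulate_edit_matrix

tree = simulate_dated_tree(n_taxa=10, crown_age=200.0, seed=7)
matrix, truth = simulate_edit_matrix(
    tree, n_ancestral_sites=700, loss_rate=0.004, gain_rate=0.0005, seed=7
)
print(f"{matrix.n_sites()} sites observed in at least one taxon "
      f"({matrix.dropped_all_zero} ancestral sites lost everywhere)")
print("edited sites per taxon:")
print(matrix.edited_counts().to_string())

table = dollo_tally(tree, matrix)
print(f"\nDollo events: {table.total_gains} gains, {table.total_losses} losses")
print(f"{len(table.ambiguous_sites)} sites sit on a root-adjacent branch: "
      "parsimony cannot tell a gain there from ancestral presence lost in the "
      "sister lineage")
print("\nper-branch events:")
print(table.to_frame().to_string(index=False))
# Losses dominating gains reproduces the progressive-loss regime typical of
# angiosperm mitochondrial RNA editing.
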