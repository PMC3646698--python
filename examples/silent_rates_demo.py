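"""Estimate branch-specific silent substitution rates and scale them to
absolute rates (ssb) on a dated tree.

Simulates a 13-taxon chronogram with a 100-fold spread of true rates and a
15 kb codon alignment, estimates pairwise synonymous divergence (NG86 + JC),
fits per-branch amounts by non-negative least squares, and divides by branch
durations to get silent substitutions per site per billion years.
"""

import numpy as np

from mitofossil.silent_rates import (
    absolute_rates,
    divergence_time_equivalent,
    ds_matrix,
    fit_branch_rates,
)
from mitofossil.synth_data import simulate_codon_alignment, simulate_dated_tree

tree = simulate_dated_tree(13, 200.0, seed=4)
rng = np.random.default_rng(4)
branches = tree.branch_ids()
ssb_true = 10 ** rng.uniform(np.log10(0.035), np.log10(3.5), size=len(branches))
ds_true = {v: s * tree.nodes[v].length / 1000 for v, s in zip(branches, ssb_true)}

aln, _ = simulate_codon_alignment(tree, ds_true, n_codons=5000, seed=4)
fitted = fit_branch_rates(tree, ds_matrix(aln))
table = absolute_rates(fitted, tree)

print("terminal-branch absolute rates (ssb = subs/site per Byr):")
truth = dict(zip(branches, ssb_true))
for _, row in table.table.iterrows():
    if row["label"]:
        t = truth[row["branch_id"]]
        print(f"  {row['label']:>4}: fitted {row['ssb']:6.3f}  true {t:6.3f}")

slowest = table.terminal_rates().min()
years = divergence_time_equivalent(69.5, slowest, 25)
print(f"\nslowest lineage: {slowest:.3f} ssb — one human generation (25 y) of "
      f"mitochondrial silent divergence would take it {years:,.0f} years")
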