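"""Group-level differential abundance between hosts and N treatments.

Agglomerates ASV counts into taxonomic groups (+1 pseudocount), then runs
the negative-binomial Wald test for the soybean-vs-maize rhizosphere
contrast and the stdN-vs-lowN contrast within maize, with
Benjamini-Hochberg adjustment, and prints the strongest shifts.
"""

from rhizovar.dastats import Contrast, agglomerate, nb_wald_test
from rhizovar.groups import GroupAssignment
from rhizovar.simulate import SimulationConfig, simulate_dataset

cfg = SimulationConfig(seed=11, n_genera=15, asvs_per_genus=(8, 15))
designs, table, tax, tree, seqs, truth = simulate_dataset(cfg)

# genus-level grouping (subgroup discovery is example 04)
groups = GroupAssignment({a: tax.genus_of()[a] for a in table.asv_ids})
gt = agglomerate(table, groups, pseudo=1)

contrasts = [
    Contrast("soybean_vs_maize", "species", "soybean", "maize",
             {"compartment": "rhizosphere"}),
    Contrast("stdN_vs_lowN_maize", "nitrogen", "stdN", "lowN",
             {"compartment": "rhizosphere", "species": "maize"}),
]
for contrast in contrasts:
    results = nb_wald_test(gt, designs, contrast)
    sig = [r for r in results if r.fdr_q < 0.05]
    print(f"\n{contrast.name}: {len(sig)}/{len(results)} groups at q < 0.05")
    for r in sorted(results, key=lambda r: r.fdr_q)[:5]:
        print(f"  {r.group:10s} log2FC = {r.log2fc:+.2f} +- {r.se:.2f}  "
              f"q = {r.fdr_q:.2e} {r.tier}")
# Positive log2FC means more abundant in the contrast's numerator
# (soybean, or standard N); *** marks q < 0.01, ** q < 0.05.
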