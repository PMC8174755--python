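"""Per-ASV variance partitioning and responsive-ASV tallies.

Fits the all-random-effects model to every ASV's log relative abundance,
tallies ASVs whose variance score exceeds 5% per factor in each soil
compartment, and compares compartments with the Yates-corrected
chi-square — the same test that, on the study's printed counts
(539/2,225 vs 300/2,014 nitrogen-responsive ASVs), gives p = 3.6e-14.
"""

from rhizovar.preprocess import subset_compartment
from rhizovar.simulate import SimulationConfig, simulate_dataset
from rhizovar.varpart import compare_compartments, partition_all, tally_responsive

cfg = SimulationConfig(seed=3, n_genera=12, asvs_per_genus=(10, 20))
designs, table, tax, tree, seqs, truth = simulate_dataset(cfg)

tallies = {}
for comp in ("rhizosphere", "bulk"):
    sub = subset_compartment(table, designs, comp)
    sub_designs = [d for d in designs if d.compartment == comp]
    profiles = partition_all(sub, sub_designs)
    print(f"\n{comp}: {len(profiles)} ASVs, responsive (>5% variance) per factor:")
    for factor in ("year", "month", "species", "rotation", "nitrogen"):
        t = tally_responsive(profiles, factor, 0.05)
        tallies[(comp, factor)] = t
        print(f"  {factor:10s} {t.count:4d}/{t.total} ({t.percent}%)")

print("\nrhizosphere vs bulk-soil enrichment of responsive ASVs:")
for factor in ("species", "nitrogen"):
    a = tallies[("rhizosphere", factor)]
    b = tallies[("bulk", factor)]
    chi2, p = compare_compartments(a.count, a.total, b.count, b.total)
    print(f"  {factor}: chi2 = {chi2:.2f}, p = {p:.3g}")
# A small p says the fraction of responsive ASVs differs between
# compartments - e.g. host-species responses concentrated in the
# rhizosphere, where root exudates reach the microbes.

print("\nprinted-count check: 539/2225 vs 300/2014 ->",
      "p = %.3g" % compare_compartments(539, 2225, 300, 2014)[1])
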