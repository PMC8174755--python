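"""Generate a synthetic rhizosphere/bulk-soil 16S survey.

Builds the full two-year factorial field design (2 years x 3 months x
2 blocks x 4 plots x 2 N levels x 2 compartments x 2 subsamples = 384
samples), simulates a phylogeny with one clade per genus, ~300 bp V4-like
sequences, and a count table with planted per-factor variance components,
then prints what was made.
"""

from rhizovar.simulate import SimulationConfig, simulate_dataset

cfg = SimulationConfig(seed=42, n_genera=20, asvs_per_genus=(10, 30))
designs, table, tax, tree, seqs, truth = simulate_dataset(cfg)

print(f"samples: {table.n_samples} "
      f"({sum(d.compartment == 'rhizosphere' for d in designs)} rhizosphere, "
      f"{sum(d.compartment == 'bulk' for d in designs)} bulk soil)")
print(f"ASVs: {table.n_asvs} in {tax.genus_of().nunique()} genera")
print(f"total reads: {table.counts.sum():,} "
      f"(median {int(sorted(table.counts.sum(axis=1))[len(designs)//2]):,} per sample)")
print(f"tree tips: {sum(1 for _ in tree.tips())}, "
      f"sequence length: {len(next(iter(seqs.sequences.values())))} bp")
print()
print("planted variance-fraction classes (per genus):")
print(truth.asv_class.value_counts().to_string())
# Each ASV's class fixes how much of its log-abundance variance each design
# factor explains; the ground truth lets every downstream estimate be
# checked against what was planted.
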