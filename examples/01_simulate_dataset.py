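"""Simulate a multi-species pooled resequencing dataset and write it to disk.

Builds a small genome with one planted sweep and one planted balancing
region, then writes the standard-format files (VCF, count table, scaffold
lengths, gene BED, truth BED) a real analysis would start from.
"""

from poolscan import SimConfig, simulate_dataset, write_dataset

cfg = SimConfig(
    n_scaffolds=3,
    scaffold_length=500_000,
    seed=7,
    sweep_regions=[("scaf1", 100_000, 200_000)],
    balancing_regions=[("scaf2", 300_000, 400_000)],
)
ds = simulate_dataset(cfg)
print(f"simulated {ds.freqs.n_sites} SNPs on {cfg.n_scaffolds} scaffolds")
print(f"samples: {', '.join(ds.sample_names)}")
print(f"planted truth: {ds.truth.regions}")

paths = write_dataset(ds, "scratch/example_dataset")
for name, path in paths.items():
    print(f"wrote {name}: {path}")
# The VCF carries diploid genotypes for the eight congener individuals and
# GT+AD (pseudodiploid genotype plus read counts) for the focal pool.
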