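"""Estimate pooled minor-allele frequencies from raw read counts.

The pooled MAF at a site is the summed frequency of all non-major alleles,
computed only where depth and variant-read support clear the filters
(>= 15 reads, >= 2 variant reads).
"""

from poolscan import AlleleCounts, site_pool_maf

examples = [
    {"A": 10, "C": 5},          # ordinary biallelic site at threshold depth
    {"A": 13, "C": 1},          # depth 14: too shallow to estimate
    {"A": 20, "C": 1},          # one variant read: likely sequencing error
    {"A": 10, "C": 4, "G": 2},  # triallelic: non-major alleles are summed
    {"A": 30},                  # no variation in the pool
]
for counts in examples:
    res = site_pool_maf(AlleleCounts("scaf1", 100, counts))
    maf = f"{res.maf:.4f}" if res.maf is not None else "-"
    print(f"counts={counts!r:32s} depth={res.depth:3d} status={res.status:18s} maf={maf}")
# Only 'ok' sites enter the window averages; the status codes record why the
# other sites were left out.
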