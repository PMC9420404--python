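"""Independent brute-force oracles used across the test suite.

These deliberately re-derive each quantity from first principles (nested
ANOVA sums of squares over allele copies, explicit interval membership,
direct Monte-Carlo expectation) rather than calling the package's own code
paths, so agreement is a real cross-check.
"""

from __future__ import annotations

import numpy as np


def wc_anova_oracle(genotypes_by_pop):
    """Weir-Cockerham a/b/c via explicit allele-copy nested ANOVA.

    Builds the 0/1 allele-copy table (copies within individuals within
    populations), computes the three mean squares from raw sums of squares,
    and converts them to variance components. Returns (a, b, c) or None for
    a skipped site (an empty population or mean sample size <= 1).
    """
    pops = []
    for g in genotypes_by_pop:
        g = np.asarray(g)
        g = g[g >= 0]
        if g.size == 0:
            return None
        pops.append(g)
    n = np.array([g.size for g in pops], dtype=float)
    n_tot = n.sum()
    r = len(pops)
    if n.mean() <= 1:
        return None
    # allele-copy means: individual mean = dosage/2, pop mean, grand mean
    ybar_i = np.array([g.mean() / 2.0 for g in pops])
    ybar = sum(g.sum() / 2.0 for g in pops) / n_tot
    ssg = ssi = ssp = 0.0
    for g, yi in zip(pops, ybar_i):
        for d in g:
            copies = np.array([1.0] * int(d) + [0.0] * (2 - int(d)))
            yij = d / 2.0
            ssg += np.sum((copies - yij) ** 2)
            ssi += 2.0 * (yij - yi) ** 2
    ssp = float(np.sum(2.0 * n * (ybar_i - ybar) ** 2))
    msg = ssg / n_tot
    msi = ssi / (n_tot - r) if n_tot > r else 0.0
    msp = ssp / (r - 1)
    nc = (n_tot - np.sum(n**2) / n_tot) / (r - 1)
    a = (msp - msi) / (2.0 * nc)
    b = (msi - msg) / 2.0
    c = msg
    return a, b, c


def window_membership_oracle(window, scaffold, pos0):
    """A 0-based position is in a half-open window iff start <= pos < end."""
    return window.scaffold == scaffold and window.start <= pos0 < window.end


def maf_mc_oracle(freq, mean_depth, n_draws, min_depth, min_variant_reads, seed):
    """Monte-Carlo expectation of the filtered folded pool-MAF estimate.

    Draws Poisson depths and binomial minor-allele reads directly and applies
    the depth/singleton filters by hand; returns (mean, se, n_kept).
    """
    rng = np.random.default_rng(seed)
    depth = rng.poisson(mean_depth, size=n_draws)
    reads = rng.binomial(depth, freq)
    minor = np.minimum(reads, depth - reads)
    kept = (depth >= min_depth) & (minor >= min_variant_reads)
    est = minor[kept] / depth[kept]
    return est.mean(), est.std(ddof=1) / np.sqrt(est.size), est.size


def interval_overlap_oracle(regions, genes):
    """All-pairs half-open interval intersection: region index -> gene ids."""
    out = {}
    for i, (rs, ra, rb) in enumerate(regions):
        hits = []
        for gs, ga, gb, gid in genes:
            if gs == rs and max(ra, ga) < min(rb, gb):
                hits.append(gid)
        out[i] = hits
    return out


def additive_distances(tree):
    """Leaf-to-leaf path distances of a nested-tuple tree.

    ``tree`` is either a (name, length) leaf or ((subtree, subtree), length).
    Returns (names, matrix).
    """

    def leaf_depths(node):
        payload, length = node
        if isinstance(payload, str):
            return {payload: length}
        out = {}
        for child in payload:
            for name, d in leaf_depths(child).items():
                out[name] = d + length
        return out

    def collect(node, acc):
        payload, _ = node
        if isinstance(payload, str):
            return
        maps = [leaf_depths(child) for child in payload]
        for i in range(len(maps)):
            for j in range(i + 1, len(maps)):
                for ni, di in maps[i].items():
                    for nj, dj in maps[j].items():
                        acc[frozenset((ni, nj))] = di + dj
        for child in payload:
            collect(child, acc)

    acc = {}
    collect(tree, acc)
    names = sorted({n for pair in acc for n in pair})
    m = np.zeros((len(names), len(names)))
    for pair, d in acc.items():
        i, j = (names.index(n) for n in pair)
        m[i, j] = m[j, i] = d
    return names, m
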