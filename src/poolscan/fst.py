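"""Weir–Cockerham F_ST: per-site variance components and windowed estimates.

The Weir & Cockerham (1984) estimator decomposes allele-frequency variance at
a biallelic site into three components: ``a`` among populations, ``b`` among
individuals within populations, and ``c`` within individuals (heterozygosity).
The per-site estimate is theta = a / (a + b + c); the windowed "weighted"
estimate is the ratio of sums, sum(a) / sum(a + b + c), over sites in the
window, which downweights noisy low-information sites. Per-site estimates may
be negative (estimator noise around zero differentiation) and are deliberately
not clamped, so that window sums stay unbiased.

Populations are the species; a sequenced pool can enter as a single
pseudodiploid genotype. Sample sizes here are diploid individuals per
population at the site (missing genotypes excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VarianceComponents:
    """Weir–Cockerham a/b/c variance components at one site."""

    scaffold: str
    pos: int
    a: float
    b: float
    c: float

    @property
    def total(self) -> float:
        return self.a + self.b + self.c


@dataclass
class PopulationAssignment:
    """Maps each genotyped sample to its population; others must be excluded.

    Mirrors the study design where each species is a population and an
    inbred reference pool is excluded from differentiation estimates.
    """

    assignment: dict[str, str]
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.assignment) & set(self.excluded)
        if overlap:
            raise ValueError(f"samples both assigned and excluded: {sorted(overlap)}")
        if len(set(self.assignment.values())) < 2:
            raise ValueError("need at least two populations")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignment.values():
            seen.setdefault(p)
        return list(seen)

    def validate_samples(self, samples: Sequence[str]) -> None:
        known = set(self.assignment) | set(self.excluded)
        missing = [s for s in samples if s not in known]
        if missing:
            raise ValueError(
                f"samples neither assigned to a population nor excluded: {missing}"
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationAssignment":
        """Read a two-column TSV (sample, population); population '-' excludes."""
        assignment: dict[str, str] = {}
        excluded: list[str] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            if pop == "-":
                excluded.append(sample)
            else:
                assignment[sample] = pop
        return cls(assignment, excluded)


def wc_components_site(
    genotypes_by_pop: Sequence[np.ndarray],
    scaffold: str = "",
    pos: int = 0,
) -> VarianceComponents | None:
    """Weir–Cockerham variance components at one biallelic site.

    ``genotypes_by_pop`` holds, per population, the derived-allele dosages
    (0/1/2) of its called diploid genotypes; missing genotypes (-1) are
    dropped. Returns None (site skipped, reason logged) when any population
    has no called genotype or the mean sample size does not exceed one
    diploid — the individual-level components are undefined there.

    Raises ValueError with fewer than two populations.
    """
    if len(genotypes_by_pop) < 2:
        raise ValueError("need >= 2 populations")
    n = []
    p = []
    h = []
    for g in genotypes_by_pop:
        g = np.asarray(g)
        g = g[g >= 0]
        if g.size == 0:
            logger.debug("site %s:%d skipped: population with no called genotype", scaffold, pos)
            return None
        n.append(g.size)
        p.append(g.mean() / 2.0)
        h.append(np.mean(g == 1))
    n = np.array(n, dtype=float)
    p = np.array(p, dtype=float)
    h = np.array(h, dtype=float)
    r = len(n)
    nbar = n.mean()
    if nbar <= 1:
        logger.debug("site %s:%d skipped: mean sample size <= 1 diploid", scaffold, pos)
        return None
    nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
    pbar = np.sum(n * p) / (r * nbar)
    s2 = np.sum(n * (p - pbar) ** 2) / ((r - 1) * nbar)
    hbar = np.sum(n * h) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return VarianceComponents(scaffold, pos, float(a), float(b), float(c))


def wc_components_matrix(
    dosages: np.ndarray,
    pop_columns: Sequence[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Weir–Cockerham components over a sites x samples matrix.

    ``dosages`` is (n_sites, n_samples) with -1 for missing; ``pop_columns``
    gives the column indices of each population's samples. Returns (a, b, c)
    arrays with NaN at skipped sites (a population with no called genotype,
    or mean sample size <= 1). Site-by-site equal to
    :func:`wc_components_site`.
    """
    if len(pop_columns) < 2:
        raise ValueError("need >= 2 populations")
    dosages = np.asarray(dosages)
    n_sites = dosages.shape[0]
    r = len(pop_columns)
    n = np.empty((n_sites, r))
    p = np.empty((n_sites, r))
    h = np.empty((n_sites, r))
    for j, cols in enumerate(pop_columns):
        sub = dosages[:, cols]
        called = sub >= 0
        n[:, j] = called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[:, j] = np.where(called, sub, 0).sum(axis=1) / (2.0 * n[:, j])
            h[:, j] = (sub == 1).sum(axis=1) / n[:, j]
    nbar = n.mean(axis=1)
    ok = (n > 0).all(axis=1) & (nbar > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rn = r * nbar
        nc = (rn - (n**2).sum(axis=1) / rn) / (r - 1)
        pbar = (n * p).sum(axis=1) / rn
        s2 = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=1) / rn
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    a = np.where(ok, a, np.nan)
    b = np.where(ok, b, np.nan)
    c = np.where(ok, c, np.nan)
    return a, b, c


def fst_site(vc: VarianceComponents) -> float | None:
    """Per-site theta = a/(a+b+c); None when the denominator is zero."""
    denom = vc.total
    if denom == 0:
        return None
    return vc.a / denom


def fst_window(
    components: Sequence[VarianceComponents],
    min_sites: int = 100,
) -> float | None:
    """Windowed weighted theta: ratio of sums over the window's sites.

    Requires at least ``min_sites`` sites with defined components; otherwise
    the window is not estimated (None). The ratio-of-sums form weights each
    site by its information content rather than averaging noisy per-site
    ratios.
    """
    if len(components) < min_sites:
        return None
    num = sum(vc.a for vc in components)
    denom = sum(vc.total for vc in components)
    if denom == 0:
        return None
    return num / denom


def fst_window_arrays(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    window_members: Sequence[np.ndarray],
    min_sites: int = 100,
    mean_of_ratios: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed theta over component arrays for a list of window memberships.

    Returns (fst, n_sites) per window; NaN where fewer than ``min_sites``
    defined sites. ``mean_of_ratios`` switches to the unweighted mean of
    per-site ratios (the weighted ratio-of-sums is the default and the
    convention used throughout).
    """
    a = np.asarray(a, float)
    tot = a + np.asarray(b, float) + np.asarray(c, float)
    defined = ~np.isnan(tot)
    fst = np.full(len(window_members), np.nan)
    n_sites = np.zeros(len(window_members), dtype=np.int64)
    for i, members in enumerate(window_members):
        m = members[defined[members]]
        n_sites[i] = m.size
        if m.size < min_sites:
            continue
        if mean_of_ratios:
            t = tot[m]
            nz = t != 0
            if nz.any():
                fst[i] = np.mean(a[m][nz] / t[nz])
        else:
            denom = tot[m].sum()
            if denom != 0:
                fst[i] = a[m].sum() / denom
    return fst, n_sites
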