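"""Synthetic multi-species pooled/individual resequencing datasets with known truth.

The generator emulates the statistical structure the genome scan assumes:
four diverged species related by the balanced tree ((A,B),(C,D)), each
represented by two diploid individuals, plus one focal population pool drawn
from species A. Per-site derived-allele frequencies start from a shared
ancestral frequency and drift independently along each branch (truncated
Gaussian increments — a cheap stand-in for genetic drift that is sufficient
to induce the among-species F_ST structure the scan measures). Pooled read
counts follow a negative-binomial depth model with binomial allele sampling
through a finite pool of chromosomes; individual genotypes are
Hardy–Weinberg draws from their species' frequency.

Selection signatures are planted region-wise: sweep regions force the focal
population toward fixation (low pooled MAF) while separating it from the
other species (high F_ST); balancing regions pull every species toward
intermediate frequencies (high MAF, low F_ST). Truth intervals are recorded
so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .phylo import encode_pseudodiploid_array

Region = tuple[str, int, int]  # scaffold, start, end — 0-based half-open

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of one simulated dataset.

    ``species_divergence`` is the per-branch drift variance in
    allele-frequency space at an ancestral frequency of 0.5 (the variance
    tapers as p(1-p) toward fixation); 0 means all species stay identical.
    ``pool_chromosomes`` is the number of chromosomes the pool samples
    (48 = 24 diploids). ``depth_dispersion`` inflates depth variance above
    Poisson: Var = mean + dispersion * mean^2.
    """

    n_scaffolds: int = 5
    scaffold_length: int = 1_000_000
    n_species: int = 4
    individuals_per_species: int = 2
    pool_chromosomes: int = 48
    species_divergence: float = 0.08
    snp_density: float = 5e-3
    mean_depth: float = 40.0
    depth_dispersion: float = 0.25
    sweep_regions: list[Region] = field(default_factory=list)
    balancing_regions: list[Region] = field(default_factory=list)
    sweep_maf_ceiling: float = 0.02
    sweep_fst_floor: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scaffolds <= 0 or self.scaffold_length <= 0:
            raise ValueError("scaffold count and length must be positive")
        if self.n_species != 4:
            raise ValueError("the drift model is defined on the fixed 4-taxon tree ((A,B),(C,D))")
        if self.individuals_per_species <= 0 or self.pool_chromosomes <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= self.species_divergence <= 0.25:
            raise ValueError("species_divergence must be in [0, 0.25]")
        if not 0 <= self.sweep_maf_ceiling < 0.5:
            raise ValueError("sweep_maf_ceiling must be in [0, 0.5)")
        if not 0 < self.sweep_fst_floor <= 1:
            raise ValueError("sweep_fst_floor must be in (0, 1]")
        if self.snp_density <= 0 or self.mean_depth <= 0 or self.depth_dispersion < 0:
            raise ValueError("snp_density and mean_depth must be positive; dispersion >= 0")
        for scaf, start, end in self.sweep_regions + self.balancing_regions:
            self._check_region((scaf, start, end))

    def _check_region(self, region: Region) -> None:
        scaf, start, end = region
        if scaf not in self.scaffold_names:
            raise ValueError(f"region {region} names unknown scaffold {scaf!r}")
        if not 0 <= start < end <= self.scaffold_length:
            raise ValueError(f"region {region} lies outside scaffold bounds")

    @property
    def scaffold_names(self) -> list[str]:
        return [f"scaf{i + 1}" for i in range(self.n_scaffolds)]

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {name: self.scaffold_length for name in self.scaffold_names}

    @property
    def species_names(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_species)]

    @property
    def individual_names(self) -> list[str]:
        return [
            f"{sp}_{i + 1}"
            for sp in self.species_names
            for i in range(self.individuals_per_species)
        ]

    @property
    def pool_name(self) -> str:
        return "pool"


@dataclass
class TruthRegions:
    """Planted ground-truth intervals (0-based half-open), typed by signature."""

    regions: list[tuple[str, int, int, str]]

    def __post_init__(self) -> None:
        for typ in ("sweep", "balancing"):
            sel = sorted(
                (r[:3] for r in self.regions if r[3] == typ), key=lambda r: (r[0], r[1])
            )
            for (s1, a1, b1), (s2, a2, b2) in zip(sel, sel[1:]):
                if s1 == s2 and a2 < b1:
                    raise ValueError(f"overlapping {typ} regions on {s1}")

    def of_type(self, typ: str) -> list[Region]:
        return [r[:3] for r in self.regions if r[3] == typ]


@dataclass
class SiteFrequencies:
    """Per-site species and focal-pool derived-allele frequencies."""

    scaffolds: np.ndarray  # object array of scaffold names, site-sorted
    positions: np.ndarray  # 1-based
    species_freqs: np.ndarray  # (n_sites, n_species)
    pool_freq: np.ndarray  # (n_sites,) focal-population frequency

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass
class Dataset:
    """A complete simulated dataset plus its ground truth."""

    cfg: SimConfig
    freqs: SiteFrequencies
    ref: np.ndarray
    alt: np.ndarray
    pool_depth: np.ndarray
    pool_alt: np.ndarray  # derived-allele (alt) reads in the pool
    genotypes: np.ndarray  # (n_sites, n_individuals) dosage 0/1/2
    truth: TruthRegions
    genes: list[tuple[str, int, int, str]]

    @property
    def pool_ref(self) -> np.ndarray:
        return self.pool_depth - self.pool_alt

    @property
    def sample_names(self) -> list[str]:
        return self.cfg.individual_names + [self.cfg.pool_name]


def _site_positions(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly placed, unique, sorted 1-based SNP positions per scaffold."""
    scafs: list[str] = []
    positions: list[np.ndarray] = []
    n_per = int(round(cfg.snp_density * cfg.scaffold_length))
    for name in cfg.scaffold_names:
        pos = np.unique(rng.integers(1, cfg.scaffold_length + 1, size=n_per))
        scafs.extend([name] * len(pos))
        positions.append(pos)
    return np.array(scafs, dtype=object), np.concatenate(positions)


def simulate_species_frequencies(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> SiteFrequencies:
    """Draw per-site species frequencies on the balanced tree ((A,B),(C,D)).

    Each site's ancestral frequency is uniform on (0, 1); every branch of
    the tree (two internal, four terminal) adds an independent Gaussian
    increment with variance species_divergence * 4p(1-p) (so the stated
    variance applies at p = 0.5), truncated to [0, 1]. The focal pool starts
    identical to species A. Sites driven to fixation by drift remain in the
    output (they are monomorphic in some or all samples, as in real data).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    scafs, pos = _site_positions(cfg, rng)
    n = len(pos)
    p0 = rng.uniform(0.0, 1.0, size=n)
    sd = np.sqrt(cfg.species_divergence * 4.0 * p0 * (1.0 - p0))
    d_ab, d_cd, d_a, d_b, d_c, d_d = (rng.normal(0.0, 1.0, size=n) * sd for _ in range(6))
    freqs = np.clip(
        np.stack(
            [p0 + d_ab + d_a, p0 + d_ab + d_b, p0 + d_cd + d_c, p0 + d_cd + d_d],
            axis=1,
        ),
        0.0,
        1.0,
    )
    return SiteFrequencies(scafs, pos, freqs, freqs[:, 0].copy())


def _region_mask(freqs: SiteFrequencies, region: Region) -> np.ndarray:
    scaf, start, end = region
    return (freqs.scaffolds == scaf) & (freqs.positions - 1 >= start) & (freqs.positions - 1 < end)


def plant_selection_regions(
    freqs: SiteFrequencies,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> SiteFrequencies:
    """Overwrite frequencies inside planted sweep and balancing regions.

    Sweeps: the focal pool (and species A) is forced to a folded MAF at or
    below ``sweep_maf_ceiling`` while the other species are moved at least
    ``sweep_fst_floor`` away in frequency — low diversity within, high
    differentiation among. Balancing regions: every species and the pool is
    pulled to intermediate frequency (0.5 plus small noise) — high diversity
    within, low differentiation among. Sites outside all regions are
    untouched; empty region lists make this a no-op.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    out = SiteFrequencies(
        freqs.scaffolds.copy(),
        freqs.positions.copy(),
        freqs.species_freqs.copy(),
        freqs.pool_freq.copy(),
    )
    for region in cfg.sweep_regions:
        cfg._check_region(region)
        m = _region_mask(out, region)
        k = int(m.sum())
        if k == 0:
            continue
        folded = rng.uniform(0.0, cfg.sweep_maf_ceiling, size=k)
        near_one = rng.random(k) < 0.5
        focal = np.where(near_one, 1.0 - folded, folded)
        sign = np.where(near_one, -1.0, 1.0)
        headroom = np.where(near_one, focal - cfg.sweep_fst_floor, 1.0 - focal - cfg.sweep_fst_floor)
        shared = rng.uniform(0.0, np.maximum(headroom, 0.0))
        others = np.clip(focal + sign * (cfg.sweep_fst_floor + shared), 0.0, 1.0)
        jitter = rng.normal(0.0, 0.02, size=(k, cfg.n_species - 1))
        out.species_freqs[m, 0] = focal
        out.species_freqs[np.ix_(m, range(1, cfg.n_species))] = np.clip(
            others[:, None] + jitter, 0.0, 1.0
        )
        out.pool_freq[m] = focal
    for region in cfg.balancing_regions:
        cfg._check_region(region)
        m = _region_mask(out, region)
        k = int(m.sum())
        if k == 0:
            continue
        out.species_freqs[m] = np.clip(
            0.5 + rng.normal(0.0, 0.05, size=(k, cfg.n_species)), 0.02, 0.98
        )
        out.pool_freq[m] = np.clip(0.5 + rng.normal(0.0, 0.05, size=k), 0.02, 0.98)
    return out


def sample_pool_counts(
    pool_freq: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample pooled (depth, derived reads) at each site.

    The pool's realised allele frequency comes from ``pool_chromosomes``
    binomial draws of the population frequency (a finite pool of 2N
    chromosomes, so rare alleles can be absent from the pool entirely).
    Depth is negative-binomial with mean ``mean_depth`` and variance
    mean + dispersion * mean^2 (Poisson in the dispersion -> 0 limit);
    derived reads are binomial in the realised frequency.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    pool_freq = np.asarray(pool_freq, float)
    n = len(pool_freq)
    realized = rng.binomial(cfg.pool_chromosomes, pool_freq) / cfg.pool_chromosomes
    if cfg.depth_dispersion == 0:
        depth = rng.poisson(cfg.mean_depth, size=n)
    else:
        shape = 1.0 / cfg.depth_dispersion
        p = shape / (shape + cfg.mean_depth)
        depth = rng.negative_binomial(shape, p, size=n)
    alt = rng.binomial(depth, realized)
    return depth.astype(np.int64), alt.astype(np.int64)


def sample_individual_genotypes(
    freqs: SiteFrequencies,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Hardy–Weinberg diploid dosages for every congener individual.

    Each individual of species s draws dosage ~ Binomial(2, p_s) at each
    site; returns (n_sites, n_species * individuals_per_species).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    n = freqs.n_sites
    cols = []
    for s in range(cfg.n_species):
        p = freqs.species_freqs[:, s]
        for _ in range(cfg.individuals_per_species):
            cols.append(rng.binomial(2, p, size=n))
    return np.stack(cols, axis=1).astype(np.int8)


def _toy_genes(cfg: SimConfig, truth: TruthRegions) -> list[tuple[str, int, int, str]]:
    """Toy annotation: one gene centred in each truth region, plus regularly
    spaced background genes outside them."""
    genes: list[tuple[str, int, int, str]] = []
    for i, (scaf, start, end, typ) in enumerate(truth.regions):
        mid = (start + end) // 2
        g_start = max(0, mid - 5_000)
        genes.append((scaf, g_start, min(cfg.scaffold_length, mid + 5_000), f"{typ}_gene_{i + 1}"))
    k = 0
    spacing = max(10_000, min(200_000, cfg.scaffold_length // 5))
    for scaf in cfg.scaffold_names:
        for start in range(spacing // 2, cfg.scaffold_length, spacing):
            end = min(start + spacing // 10, cfg.scaffold_length)
            if any(s == scaf and start < e and end > g for s, g, e, _ in truth.regions):
                continue
            k += 1
            genes.append((scaf, start, end, f"bg_gene_{k}"))
    genes.sort(key=lambda g: (g[0], g[1]))
    return genes


def simulate_dataset(cfg: SimConfig) -> Dataset:
    """Run the full generator: frequencies, planted regions, counts, genotypes.

    All randomness flows from ``cfg.seed`` through one generator, so a fixed
    config yields bitwise-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = simulate_species_frequencies(cfg, rng)
    freqs = plant_selection_regions(freqs, cfg, rng)
    n = freqs.n_sites
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    depth, alt_reads = sample_pool_counts(freqs.pool_freq, cfg, rng)
    genotypes = sample_individual_genotypes(freqs, cfg, rng)
    truth = TruthRegions(
        [(s, a, b, "sweep") for s, a, b in cfg.sweep_regions]
        + [(s, a, b, "balancing") for s, a, b in cfg.balancing_regions]
    )
    return Dataset(
        cfg=cfg,
        freqs=freqs,
        ref=_BASES[ref_idx],
        alt=_BASES[alt_idx],
        pool_depth=depth,
        pool_alt=alt_reads,
        genotypes=genotypes,
        truth=truth,
        genes=_toy_genes(cfg, truth),
    )


def benchmark_config(seed: int = 0, planted: bool = True) -> SimConfig:
    """The package's standard power-evaluation configuration.

    Twenty 2-Mb scaffolds at 40x pooled depth with strong planted effects:
    five 100-kb sweep regions and three 150-kb balancing regions (when
    ``planted``). Region sizes are kept well below the scan's quantile-tail
    mass — an empirical-tail procedure can only confirm outliers that are
    rarer than its tails, so truth regions jointly occupy ~2% of windows
    against the 5%/1% thresholds.
    """
    sweeps = [(f"scaf{i}", 500_000, 600_000) for i in (1, 3, 5, 7, 9)]
    balancing = [(f"scaf{i}", 1_200_000, 1_350_000) for i in (2, 4, 6)]
    return SimConfig(
        n_scaffolds=20,
        scaffold_length=2_000_000,
        mean_depth=40.0,
        sweep_regions=sweeps if planted else [],
        balancing_regions=balancing if planted else [],
        sweep_maf_ceiling=0.02,
        sweep_fst_floor=0.6,
        seed=seed,
    )


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset as plain-text standard formats.

    Emits a multisample VCF (GT for individuals; GT+AD for the pool, with
    the pool genotype coded pseudodiploid), a per-site allele-count TSV, a
    scaffold-length TSV (fai-style columns), a gene BED and a truth-region
    BED. All coordinates are 1-based in the VCF/TSV and 0-based half-open in
    BED. Round-trips losslessly through the package's readers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = ds.cfg
    paths = {
        "vcf": out / "sim.vcf",
        "counts": out / "pool_counts.tsv",
        "scaffolds": out / "scaffolds.tsv",
        "genes": out / "genes.bed",
        "truth": out / "truth.bed",
    }
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    pool_gt = encode_pseudodiploid_array(ds.pool_ref, ds.pool_alt)
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        for name, length in cfg.scaffold_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.sample_names)
            + "\n"
        )
        for i in range(ds.freqs.n_sites):
            cells = [gt_str[int(g)] for g in ds.genotypes[i]]
            cells.append(f"{gt_str[int(pool_gt[i])]}:{ds.pool_ref[i]},{ds.pool_alt[i]}")
            fh.write(
                f"{ds.freqs.scaffolds[i]}\t{ds.freqs.positions[i]}\t.\t{ds.ref[i]}\t"
                f"{ds.alt[i]}\t999\t.\t.\tGT:AD\t" + "\t".join(cells) + "\n"
            )
    with open(paths["counts"], "w") as fh:
        fh.write("scaffold\tpos\tref\talt\trefCount\taltCount\n")
        for i in range(ds.freqs.n_sites):
            fh.write(
                f"{ds.freqs.scaffolds[i]}\t{ds.freqs.positions[i]}\t{ds.ref[i]}\t"
                f"{ds.alt[i]}\t{ds.pool_ref[i]}\t{ds.pool_alt[i]}\n"
            )
    with open(paths["scaffolds"], "w") as fh:
        for name, length in cfg.scaffold_lengths.items():
            fh.write(f"{name}\t{length}\n")
    with open(paths["genes"], "w") as fh:
        for scaf, start, end, gid in ds.genes:
            fh.write(f"{scaf}\t{start}\t{end}\t{gid}\n")
    with open(paths["truth"], "w") as fh:
        for scaf, start, end, typ in ds.truth.regions:
            fh.write(f"{scaf}\t{start}\t{end}\t{typ}\n")
    return paths
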