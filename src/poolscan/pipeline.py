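"""End-to-end orchestration: simulate or load, filter, window, scan, tree.

A single :class:`RunConfig` carries either a :class:`~poolscan.simulate.SimConfig`
(simulate-and-scan) or paths to real inputs (VCF + scaffold lengths + genes +
population map), plus every analysis parameter with the scan's standard
defaults: pooled sites need >= 15 reads and >= 2 variant reads, windows are
50 kb sliding by 25 kb, F_ST needs >= 100 sites per window, candidate regions
need >= 2 consecutive 5%-tail windows with a 1%-tail member. All randomness
flows from one seed, so a fixed config produces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as _io
from . import scan as _scan
from . import sites as _sites
from . import windows as _windows
from .fst import PopulationAssignment, fst_window_arrays, wc_components_matrix
from .phylo import (
    Tree,
    bootstrap_support,
    encode_pseudodiploid_array,
    ibs_distance_matrix,
    neighbor_joining,
)
from .scan import CandidateRegion, ScanConfig
from .simulate import Dataset, SimConfig, simulate_dataset
from .windows import Window

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one scan run needs; exactly one input source must be set."""

    sim: SimConfig | None = None
    vcf: str | None = None
    scaffold_lengths: str | None = None
    genes: str | None = None
    pop_map: str | None = None
    pool_sample: str = "pool"

    min_depth: int = 15
    min_variant_reads: int = 2
    max_qual: float = 999
    indel_margin: int = 3
    window_size: int = 50_000
    window_step: int = 25_000
    min_fst_sites: int = 100
    min_maf_sites: int = 1
    include_monomorphic: bool = False
    mean_of_ratios: bool = False
    scan: ScanConfig = field(default_factory=ScanConfig)
    bootstrap_reps: int = 100
    tree_max_sites: int = 20_000

    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.vcf is None):
            raise ValueError("exactly one of sim config or VCF input must be given")
        if self.vcf is not None and self.scaffold_lengths is None:
            raise ValueError("real-data runs need a scaffold-length file")


@dataclass
class ScanResult:
    """In-memory bundle of everything a run produced."""

    window_stats: pd.DataFrame
    windows: list[Window]
    regions: list[CandidateRegion]
    tree: Tree | None
    fixed_differences: pd.DataFrame
    summary: dict
    filter_counts: dict


def _sim_arrays(ds: Dataset):
    """Unpack a simulated dataset into the array bundle the scan consumes."""
    pop_assignment = PopulationAssignment(
        {
            **{name: name.split("_")[0] for name in ds.cfg.individual_names},
            ds.cfg.pool_name: ds.cfg.species_names[0],
        }
    )
    return dict(
        scaffolds=ds.freqs.scaffolds,
        positions=ds.freqs.positions,
        quals=np.full(ds.freqs.n_sites, 999.0),
        is_indel=np.zeros(ds.freqs.n_sites, bool),
        is_biallelic_snp=np.ones(ds.freqs.n_sites, bool),
        genotypes=ds.genotypes,
        sample_names=ds.cfg.individual_names,
        pool_ref=ds.pool_ref,
        pool_alt=ds.pool_alt,
        pool_name=ds.cfg.pool_name,
        scaffold_lengths=ds.cfg.scaffold_lengths,
        genes=ds.genes,
        pop_assignment=pop_assignment,
        truth=ds.truth,
    )


def _real_arrays(cfg: RunConfig):
    vt = _io.read_vcf(cfg.vcf, pool_samples=[cfg.pool_sample])
    pool_ref, pool_alt = vt.pool_ad[cfg.pool_sample]
    if cfg.pop_map is None:
        raise ValueError("real-data runs need a population map")
    pop_assignment = PopulationAssignment.from_tsv(cfg.pop_map)
    pop_assignment.validate_samples(vt.samples)
    individuals = [s for s in vt.samples if s != cfg.pool_sample]
    ind_cols = [vt.samples.index(s) for s in individuals]
    return dict(
        scaffolds=vt.scaffolds,
        positions=vt.positions,
        quals=vt.quals,
        is_indel=vt.is_indel,
        is_biallelic_snp=vt.is_biallelic_snp,
        genotypes=vt.genotypes[:, ind_cols],
        sample_names=individuals,
        pool_ref=pool_ref,
        pool_alt=pool_alt,
        pool_name=cfg.pool_sample,
        scaffold_lengths=_io.read_scaffold_lengths(cfg.scaffold_lengths),
        genes=_io.read_genes(cfg.genes) if cfg.genes else [],
        pop_assignment=pop_assignment,
        truth=None,
    )


def run_scan(cfg: RunConfig) -> ScanResult:
    """Run the full scan and (optionally) write the artifact bundle.

    Steps: acquire sites (simulate or read), apply the retention filters,
    estimate pooled MAF per site, tile windows and aggregate mean MAF and
    weighted F_ST, flag joint quantile-tail outliers, merge consecutive runs
    into candidate regions, annotate genes, build the IBS/NJ tree with
    bootstrap supports, and count fixed differences per conspecific pair.
    """
    logging.basicConfig(level=cfg.log_level)
    rng = np.random.default_rng(cfg.seed)
    data = _sim_arrays(simulate_dataset(cfg.sim)) if cfg.sim is not None else _real_arrays(cfg)

    # --- retention filters (quality cap, biallelic SNPs, indel proximity)
    keep = _sites.filter_mask(
        data["scaffolds"],
        data["positions"],
        data["quals"],
        data["is_indel"],
        data["is_biallelic_snp"],
        max_qual=cfg.max_qual,
        indel_margin=cfg.indel_margin,
    )
    filter_counts = {
        "input_records": int(len(keep)),
        "retained_snps": int(keep.sum()),
        "removed": int((~keep).sum()),
    }
    scaffolds = data["scaffolds"][keep]
    pos = data["positions"][keep]
    pool_ref = np.asarray(data["pool_ref"])[keep]
    pool_alt = np.asarray(data["pool_alt"])[keep]
    genotypes = np.asarray(data["genotypes"])[keep]

    # --- per-site pooled MAF with depth/singleton filters
    maf, maf_status = _sites.pool_maf_biallelic(
        pool_ref, pool_alt, min_depth=cfg.min_depth, min_variant_reads=cfg.min_variant_reads
    )
    codes, counts = np.unique(maf_status, return_counts=True)
    filter_counts["maf_sites"] = {
        _sites.MAF_STATUS_CODES[int(c)]: int(n) for c, n in zip(codes, counts)
    }

    # --- windows
    windows = _windows.tile_windows(
        data["scaffold_lengths"], size=cfg.window_size, step=cfg.window_step
    )
    members = _windows.assign_sites_to_windows(windows, scaffolds, pos - 1)

    maf_vals = maf.copy()
    if cfg.include_monomorphic:
        maf_vals[maf_status == 3] = 0.0
    mean_maf = np.full(len(windows), np.nan)
    n_maf_sites = np.zeros(len(windows), dtype=np.int64)
    for i, m in enumerate(members):
        vals = maf_vals[m]
        vals = vals[~np.isnan(vals)]
        n_maf_sites[i] = vals.size
        if vals.size >= cfg.min_maf_sites:
            mean_maf[i] = vals.mean()

    # --- F_ST with the pool as one pseudodiploid genotype in its population
    pool_dosage = encode_pseudodiploid_array(
        pool_ref, pool_alt, min_depth=cfg.min_depth, min_variant_reads=cfg.min_variant_reads
    )
    dosages = np.column_stack([genotypes, pool_dosage])
    all_samples = list(data["sample_names"]) + [data["pool_name"]]
    pa: PopulationAssignment = data["pop_assignment"]
    pop_cols = [
        np.array([i for i, s in enumerate(all_samples) if pa.assignment.get(s) == pop])
        for pop in pa.populations
    ]
    a, b, c = wc_components_matrix(dosages, pop_cols)
    fst, n_fst_sites = fst_window_arrays(
        a, b, c, members, min_sites=cfg.min_fst_sites, mean_of_ratios=cfg.mean_of_ratios
    )

    window_stats = pd.DataFrame(
        {
            "scaffold": [w.scaffold for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_maf_sites": n_maf_sites,
            "mean_maf": mean_maf,
            "n_fst_sites": n_fst_sites,
            "fst": fst,
        }
    )

    # --- joint outlier scan over windows with both statistics defined
    analyzed = window_stats.dropna(subset=["mean_maf", "fst"])
    regions: list[CandidateRegion] = []
    if len(analyzed) >= 2:
        flagged = _scan.joint_quantile_flags(analyzed, cfg.scan)
        regions = _scan.merge_outlier_runs(flagged, windows, cfg.scan)
        regions = _scan.annotate_regions(regions, data["genes"])
        n_run_flagged = {
            mode: int(flagged[f"{mode}_run"].sum()) for mode in _scan.MODES
        }
    else:
        n_run_flagged = {mode: 0 for mode in _scan.MODES}

    # --- IBS/NJ tree (site-subsampled for tractable bootstrapping)
    tree = None
    if cfg.tree_max_sites > 0 and dosages.shape[0] >= 1 and dosages.shape[1] >= 3:
        n_sites = dosages.shape[0]
        if n_sites > cfg.tree_max_sites:
            sel = np.sort(rng.choice(n_sites, size=cfg.tree_max_sites, replace=False))
        else:
            sel = np.arange(n_sites)
        if cfg.bootstrap_reps > 0:
            tree = bootstrap_support(
                dosages[sel].T,
                all_samples,
                n_reps=cfg.bootstrap_reps,
                seed=int(rng.integers(2**31)),
            )
        else:
            tree = neighbor_joining(ibs_distance_matrix(dosages[sel].T, all_samples))

    # --- fixed differences between conspecific pairs, non-overlapping windows
    nov_windows = _windows.tile_windows(
        data["scaffold_lengths"], size=cfg.window_size, step=cfg.window_size
    )
    pairs = []
    by_pop: dict[str, list[int]] = {}
    for i, s in enumerate(data["sample_names"]):
        by_pop.setdefault(pa.assignment.get(s, "?"), []).append(i)
    for pop, idxs in by_pop.items():
        for i in range(len(idxs)):
            for j in range(i + 1, len(idxs)):
                pairs.append((data["sample_names"][idxs[i]], data["sample_names"][idxs[j]], idxs[i], idxs[j]))
    fd_frames = []
    for name_a, name_b, ia, ib in pairs:
        fd = _windows.window_fixed_differences(
            genotypes[:, ia], genotypes[:, ib], scaffolds, pos - 1, nov_windows
        )
        fd.insert(0, "pair", f"{name_a}-{name_b}")
        fd_frames.append(fd)
    fixed_diff = (
        pd.concat(fd_frames, ignore_index=True)
        if fd_frames
        else pd.DataFrame(columns=["pair", "scaffold", "start", "end", "fixed_differences"])
    )

    summary = {
        "n_windows_total": len(windows),
        "n_windows_analyzed": int(len(analyzed)),
        "n_run_flagged": n_run_flagged,
        "n_regions": {
            mode: sum(1 for r in regions if r.mode == mode) for mode in _scan.MODES
        },
        "seed": cfg.seed,
    }
    if data["truth"] is not None:
        truth = data["truth"]
        for mode in _scan.MODES:
            planted = truth.of_type(mode)
            rec, false = _scan.match_truth([r for r in regions if r.mode == mode], planted)
            summary[f"{mode}_truth"] = {
                "planted": len(planted),
                "recovered": rec,
                "false_regions": false,
            }

    result = ScanResult(
        window_stats=window_stats,
        windows=windows,
        regions=regions,
        tree=tree,
        fixed_differences=fixed_diff,
        summary=summary,
        filter_counts=filter_counts,
    )
    if cfg.out_dir is not None:
        write_results(result, cfg)
    return result


def write_results(result: ScanResult, cfg: RunConfig) -> dict[str, Path]:
    """Write the artifact bundle as plain-text files (no timestamps, so a
    fixed config and seed reproduce the bundle byte for byte)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "window_stats": out / "window_stats.tsv",
        "regions_bed": out / "regions.bed",
        "regions_tsv": out / "regions.tsv",
        "tree": out / "tree.nwk",
        "fixed_differences": out / "fixed_differences.tsv",
        "summary": out / "summary.json",
        "params": out / "run_params.json",
    }
    result.window_stats.to_csv(paths["window_stats"], sep="\t", index=False, float_format="%.8g")
    _scan.regions_to_bed(result.regions, paths["regions_bed"])
    with open(paths["regions_tsv"], "w") as fh:
        fh.write("mode\tscaffold\tstart\tend\tn_windows\tgenes\tmember_windows\n")
        for r in sorted(result.regions, key=lambda r: (r.mode, r.scaffold, r.start)):
            mw = ",".join(f"{s}-{e}" for s, e in r.member_windows)
            fh.write(
                f"{r.mode}\t{r.scaffold}\t{r.start}\t{r.end}\t{r.n_windows}\t"
                f"{';'.join(r.genes)}\t{mw}\n"
            )
    if result.tree is not None:
        paths["tree"].write_text(result.tree.newick() + "\n")
    result.fixed_differences.to_csv(paths["fixed_differences"], sep="\t", index=False)
    with open(paths["summary"], "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    params = asdict(cfg)
    params["filter_counts"] = result.filter_counts
    with open(paths["params"], "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return paths
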