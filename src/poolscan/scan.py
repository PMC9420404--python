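"""Two-variable quantile-tail outlier scan for sweep and balancing candidates.

Window mean MAF and windowed F_ST are jointly informative: a selective sweep
in the focal population leaves consecutive windows with unusually low pooled
MAF and unusually high among-species F_ST, while balancing selection leaves
the converse pattern (high MAF, low F_ST). The scan operationalises joint
"visual" outlier detection with two empirical-quantile thresholds computed
genome-wide over all analysed windows:

* a membership threshold (``run_tail``, default 5%) defines which windows
  can participate in an outlier run;
* runs of at least ``min_run`` consecutive flagged windows become candidate
  regions only if at least one member window falls in the stricter
  ``extreme_tail`` (default 1%) tails of *both* distributions.

Only windows with both statistics defined are analysed; a window with no
estimate breaks a run (consecutiveness is over the ordered tiling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MODES = ("sweep", "balancing")


@dataclass(frozen=True)
class ScanConfig:
    """Outlier-scan thresholds.

    ``extreme_tail`` is the confirmation quantile (a reported region must
    contain a window in the 1% tails of both MAF and F_ST by default);
    ``run_tail`` the looser membership quantile for run construction;
    ``min_run`` the minimum number of consecutive flagged windows.
    """

    extreme_tail: float = 0.01
    run_tail: float = 0.05
    min_run: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.extreme_tail <= self.run_tail < 0.5:
            raise ValueError("need 0 < extreme_tail <= run_tail < 0.5")
        if self.min_run < 2:
            raise ValueError("min_run must be >= 2 (a single window is not a run)")


@dataclass
class CandidateRegion:
    """A merged run of consecutive outlier windows of one signature type."""

    scaffold: str
    start: int
    end: int
    mode: str  # sweep | balancing
    member_windows: list[tuple[int, int]]  # (start, end) of each member
    has_extreme_window: bool
    genes: list[str] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.member_windows)


def joint_quantile_flags(window_stats: pd.DataFrame, cfg: ScanConfig = ScanConfig()) -> pd.DataFrame:
    """Flag windows in the joint quantile tails of (mean MAF, F_ST).

    ``window_stats`` must contain columns scaffold/start/end/mean_maf/fst and
    be restricted to windows with both statistics defined. For each mode the
    window is run-flagged when both statistics lie strictly beyond their
    ``run_tail`` empirical quantiles in the mode's directions (sweep: low
    MAF and high F_ST; balancing: high MAF and low F_ST), and
    extreme-flagged when strictly beyond the ``extreme_tail`` quantiles.
    Quantiles are computed genome-wide over the analysed windows with linear
    interpolation; comparisons are strict, so a degenerate (constant)
    distribution flags nothing.
    """
    df = window_stats.copy()
    if df["mean_maf"].isna().any() or df["fst"].isna().any():
        raise ValueError("window_stats must be restricted to windows with both statistics defined")
    if len(df) < 2:
        raise ValueError("need at least 2 analysed windows to define quantile tails")
    maf = df["mean_maf"].to_numpy(float)
    fst = df["fst"].to_numpy(float)
    for name, tail in (("run", cfg.run_tail), ("extreme", cfg.extreme_tail)):
        maf_lo, maf_hi = np.quantile(maf, [tail, 1 - tail])
        fst_lo, fst_hi = np.quantile(fst, [tail, 1 - tail])
        df[f"sweep_{name}"] = (maf < maf_lo) & (fst > fst_hi)
        df[f"balancing_{name}"] = (maf > maf_hi) & (fst < fst_lo)
    return df


def merge_outlier_runs(
    flagged: pd.DataFrame,
    windows: Sequence,
    cfg: ScanConfig = ScanConfig(),
) -> list[CandidateRegion]:
    """Merge consecutive run-flagged windows into reported candidate regions.

    ``windows`` is the full ordered tiling (so gaps — windows with no
    estimate, absent from ``flagged`` — break runs). Maximal runs of at
    least ``min_run`` consecutive run-flagged windows of one mode are
    reported only if at least one member is extreme-flagged; the region span
    is the union of member window intervals.
    """
    order = {(w.scaffold, w.start): i for i, w in enumerate(windows)}
    info: dict[int, dict] = {}
    for row in flagged.itertuples():
        key = (row.scaffold, row.start)
        if key not in order:
            raise ValueError(f"flagged window {key} not in the tiling")
        info[order[key]] = {
            "end": row.end,
            "sweep_run": bool(row.sweep_run),
            "sweep_extreme": bool(row.sweep_extreme),
            "balancing_run": bool(row.balancing_run),
            "balancing_extreme": bool(row.balancing_extreme),
        }

    regions: list[CandidateRegion] = []
    for mode in MODES:
        run: list[int] = []

        def close(run: list[int]) -> None:
            if len(run) < cfg.min_run:
                return
            extreme = any(info[i][f"{mode}_extreme"] for i in run)
            if not extreme:
                return
            members = [(windows[i].start, windows[i].end) for i in run]
            regions.append(
                CandidateRegion(
                    scaffold=windows[run[0]].scaffold,
                    start=min(m[0] for m in members),
                    end=max(m[1] for m in members),
                    mode=mode,
                    member_windows=members,
                    has_extreme_window=True,
                )
            )

        for i, w in enumerate(windows):
            flaggable = (
                i in info
                and info[i][f"{mode}_run"]
                and (not run or windows[run[-1]].scaffold == w.scaffold)
            )
            if flaggable:
                run.append(i)
            else:
                close(run)
                run = [i] if i in info and info[i][f"{mode}_run"] else []
        close(run)
    regions.sort(key=lambda r: (r.mode, r.scaffold, r.start))
    return regions


def annotate_regions(
    regions: Sequence[CandidateRegion],
    genes: Sequence[tuple[str, int, int, str]],
) -> list[CandidateRegion]:
    """Attach the ids of genes overlapping each region (any shared bp).

    Genes and regions are 0-based half-open; a gene starting exactly at the
    region end does not overlap. Gene ids are reported in positional order.
    """
    by_scaf: dict[str, list[tuple[int, int, str]]] = {}
    for scaf, start, end, gid in genes:
        by_scaf.setdefault(scaf, []).append((start, end, gid))
    for lst in by_scaf.values():
        lst.sort()
    for region in regions:
        region.genes = [
            gid
            for start, end, gid in by_scaf.get(region.scaffold, [])
            if start < region.end and end > region.start
        ]
    return list(regions)


def regions_to_bed(regions: Sequence[CandidateRegion], path) -> None:
    """BED export: name = mode, score = member-window count."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.scaffold, r.start, r.mode)):
            fh.write(f"{r.scaffold}\t{r.start}\t{r.end}\t{r.mode}\t{r.n_windows}\n")


def match_truth(
    regions: Sequence[CandidateRegion],
    truth: Sequence[tuple[str, int, int]],
) -> tuple[int, int]:
    """(recovered truth regions, false regions) by >= 1 bp overlap."""
    recovered = 0
    for scaf, start, end in truth:
        if any(r.scaffold == scaf and r.start < end and r.end > start for r in regions):
            recovered += 1
    false = sum(
        1
        for r in regions
        if not any(
            r.scaffold == scaf and r.start < end and r.end > start for scaf, start, end in truth
        )
    )
    return recovered, false
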