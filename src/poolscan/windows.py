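"""Genomic window tiling and per-window aggregation.

Windows are half-open 0-based intervals laid along each scaffold at a fixed
step; the default tiling (50 kb windows, 25 kb step) means each position is
covered by up to two windows and window statistics vary smoothly along a
scaffold. Windows are addressed by their start coordinate, matching how
sliding-window scans are plotted. Trailing partial windows are emitted,
truncated at the scaffold end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sites import SiteMAF

WINDOW_SIZE = 50_000
WINDOW_STEP = 25_000
MIN_FST_SITES = 100
MIN_MAF_SITES = 1


@dataclass(frozen=True, order=True)
class Window:
    scaffold: str
    start: int  # 0-based inclusive
    end: int  # exclusive

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad window [{self.start}, {self.end})")

    def __contains__(self, pos0: int) -> bool:
        """Membership of a 0-based position."""
        return self.start <= pos0 < self.end


def tile_windows(
    scaffold_lengths: Mapping[str, int],
    size: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
) -> list[Window]:
    """Tile every scaffold with sliding windows of ``size`` bp at ``step`` bp.

    Windows start at 0, step, 2*step, ... for every start strictly inside the
    scaffold; the final window is truncated at the scaffold end. Requires
    size >= step > 0 (so the tiling covers every base).
    """
    if not (size >= step > 0):
        raise ValueError(f"need size >= step > 0, got size={size} step={step}")
    out: list[Window] = []
    for scaf, length in scaffold_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length {length} for scaffold {scaf}")
        for start in range(0, length, step):
            out.append(Window(scaf, start, min(start + size, length)))
    return out


def _windows_frame(windows: Sequence[Window]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scaffold": [w.scaffold for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
        }
    )


def assign_sites_to_windows(
    windows: Sequence[Window],
    scaffolds: np.ndarray,
    positions0: np.ndarray,
) -> list[np.ndarray]:
    """Indices of the sites falling in each window (0-based positions).

    Sites must be position-sorted within each scaffold; a site contributes to
    every window that overlaps it.
    """
    scaffolds = np.asarray(scaffolds)
    positions0 = np.asarray(positions0)
    by_scaf: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for scaf in np.unique(scaffolds):
        idx = np.flatnonzero(scaffolds == scaf)
        pos = positions0[idx]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions not sorted on scaffold {scaf}")
        by_scaf[str(scaf)] = (idx, pos)
    out: list[np.ndarray] = []
    empty = np.empty(0, dtype=np.int64)
    for w in windows:
        if w.scaffold not in by_scaf:
            out.append(empty)
            continue
        idx, pos = by_scaf[w.scaffold]
        lo = np.searchsorted(pos, w.start, side="left")
        hi = np.searchsorted(pos, w.end, side="left")
        out.append(idx[lo:hi])
    return out


def window_mean_maf(
    site_mafs: Iterable[SiteMAF],
    windows: Sequence[Window],
    min_sites_maf: int = MIN_MAF_SITES,
    include_monomorphic: bool = False,
) -> pd.DataFrame:
    """Mean pooled MAF per window over estimable sites.

    Status-``ok`` sites contribute their MAF; sites with status
    ``monomorphic`` contribute 0 only when ``include_monomorphic`` is set
    (whether invariant sites belong in the average is a convention choice —
    both are supported). Windows with fewer than ``min_sites_maf``
    qualifying sites get NaN. A site falling in two overlapping windows
    contributes to both.
    """
    sites = list(site_mafs)
    scafs = np.array([s.scaffold for s in sites], dtype=object)
    pos0 = np.array([s.pos - 1 for s in sites], dtype=np.int64)
    maf = np.array(
        [
            s.maf
            if s.status == "ok"
            else (0.0 if (include_monomorphic and s.status == "monomorphic") else np.nan)
            for s in sites
        ],
        dtype=float,
    )
    if len(sites):
        order = np.lexsort((pos0, scafs.astype(str)))
        scafs, pos0, maf = scafs[order], pos0[order], maf[order]
    df = _windows_frame(windows)
    means = np.full(len(windows), np.nan)
    counts = np.zeros(len(windows), dtype=np.int64)
    if len(sites):
        for i, members in enumerate(assign_sites_to_windows(windows, scafs, pos0)):
            vals = maf[members]
            vals = vals[~np.isnan(vals)]
            counts[i] = vals.size
            if vals.size >= min_sites_maf:
                means[i] = vals.mean()
    df["mean_maf"] = means
    df["n_maf_sites"] = counts
    return df


def window_fixed_differences(
    genotypes_a: np.ndarray,
    genotypes_b: np.ndarray,
    scaffolds: np.ndarray,
    positions0: np.ndarray,
    windows: Sequence[Window],
) -> pd.DataFrame:
    """Count fixed differences between two individuals per window.

    A fixed difference is a site where the two individuals are opposite
    homozygotes (dosage 0 vs 2). Missing genotypes (-1) never count. The
    same site set must underlie both vectors. Intended for non-overlapping
    windows, where per-window counts sum to the genome-wide total.
    """
    a = np.asarray(genotypes_a)
    b = np.asarray(genotypes_b)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must cover the same sites")
    fixed = ((a == 0) & (b == 2)) | ((a == 2) & (b == 0))
    df = _windows_frame(windows)
    counts = np.zeros(len(windows), dtype=np.int64)
    for i, members in enumerate(assign_sites_to_windows(windows, scaffolds, positions0)):
        counts[i] = int(fixed[members].sum())
    df["fixed_differences"] = counts
    return df


def rpkm(
    mapped_pairs_in_feature: float,
    feature_length: int,
    total_mapped_pairs: float,
) -> float:
    """Read pairs per kilobase of feature per million mapped pairs."""
    if feature_length <= 0 or total_mapped_pairs <= 0:
        raise ValueError("feature_length and total_mapped_pairs must be positive")
    return mapped_pairs_in_feature / (feature_length / 1e3) / (total_mapped_pairs / 1e6)


def relative_window_depth(window_depths: np.ndarray) -> np.ndarray:
    """Scale window depths by the median over all windows (median maps to 1)."""
    d = np.asarray(window_depths, dtype=float)
    if d.size == 0:
        raise ValueError("no window depths given")
    med = np.median(d)
    if med <= 0:
        raise ValueError("median window depth must be positive")
    return d / med
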