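"""Per-site variant filters and the pooled minor-allele-frequency estimator.

Pool-seq data give read counts per allele at each site rather than genotypes.
The minor allele frequency (MAF) of the pool is estimated directly from those
counts: depth is the total read count, the major allele is the one with the
most reads, and the MAF is the summed frequency of all non-major alleles.
Sites with too little depth, or whose only evidence of variation is a single
read (likely a sequencing error), are excluded rather than estimated.

Variant records ascertained across samples are additionally filtered to
biallelic SNPs at the caller's maximum quality that are not within a few
positions of a called indel, where alignment artifacts concentrate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# Retention defaults for pooled sites: minimum aligned reads, and minimum
# reads supporting a variant allele before it counts as real variation.
MIN_DEPTH = 15
MIN_VARIANT_READS = 2

#: Maximum (capped) variant quality emitted by the caller; only records at
#: the cap are retained.
MAX_QUAL = 999

#: SNPs within this many positions of a called indel are discarded.
INDEL_MARGIN = 3

VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class AlleleCounts:
    """Read counts per allele for one pool at one site."""

    scaffold: str
    pos: int  # 1-based
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError(f"empty allele counts at {self.scaffold}:{self.pos}")
        for allele, n in self.counts.items():
            if allele not in VALID_BASES:
                raise ValueError(f"invalid allele {allele!r} at {self.scaffold}:{self.pos}")
            if n < 0:
                raise ValueError(f"negative count for {allele} at {self.scaffold}:{self.pos}")
        if sum(self.counts.values()) == 0:
            raise ValueError(f"all-zero allele counts at {self.scaffold}:{self.pos}")

    @property
    def depth(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class SiteMAF:
    """Pooled MAF estimate (or the reason none was made) at one site.

    ``maf`` is defined only for status ``ok``. For a biallelic site it lies
    in [0, 0.5]; with k observed alleles the non-major sum can reach
    (k-1)/k, so the general bound is [0, 1).
    """

    scaffold: str
    pos: int
    depth: int
    status: str  # ok | low_depth | singleton_variant | monomorphic
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.status == "ok":
            if self.maf is None or not (0.0 <= self.maf < 1.0):
                raise ValueError(f"status ok requires maf in [0, 1), got {self.maf}")
        elif self.maf is not None:
            raise ValueError(f"maf must be None for status {self.status}")


def site_pool_maf(
    counts: AlleleCounts,
    min_depth: int = MIN_DEPTH,
    min_variant_reads: int = MIN_VARIANT_READS,
) -> SiteMAF:
    """Estimate the pooled minor allele frequency at one site from read counts.

    The major allele is the one with the highest count (ties broken toward the
    lexicographically smallest allele, deterministically). The MAF is the sum
    of all non-major read counts divided by depth.

    Sites are not estimated when depth < ``min_depth`` (status ``low_depth``),
    when the non-major evidence is fewer than ``min_variant_reads`` reads
    (status ``singleton_variant`` — a single supporting read is
    indistinguishable from error), or when no non-major reads exist at all
    (status ``monomorphic``).
    """
    depth = counts.depth
    base = dict(scaffold=counts.scaffold, pos=counts.pos, depth=depth)
    if depth < min_depth:
        return SiteMAF(status="low_depth", **base)
    # tie-break: max count, then smallest allele string
    major = min(counts.counts, key=lambda a: (-counts.counts[a], a))
    nonmajor = depth - counts.counts[major]
    if nonmajor == 0:
        return SiteMAF(status="monomorphic", **base)
    if nonmajor < min_variant_reads:
        return SiteMAF(status="singleton_variant", **base)
    return SiteMAF(status="ok", maf=nonmajor / depth, **base)


def pool_maf_biallelic(
    ref_counts: np.ndarray,
    alt_counts: np.ndarray,
    min_depth: int = MIN_DEPTH,
    min_variant_reads: int = MIN_VARIANT_READS,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised pooled MAF over arrays of biallelic ref/alt read counts.

    Returns ``(maf, status)`` where ``maf`` is NaN wherever no estimate is
    made and ``status`` is an integer code array (0 ok, 1 low_depth,
    2 singleton_variant, 3 monomorphic). Equivalent site-by-site to
    :func:`site_pool_maf` on two-allele counts.
    """
    ref_counts = np.asarray(ref_counts, dtype=np.int64)
    alt_counts = np.asarray(alt_counts, dtype=np.int64)
    depth = ref_counts + alt_counts
    minor = np.minimum(ref_counts, alt_counts)
    status = np.zeros(depth.shape, dtype=np.int8)
    status[minor == 0] = 3
    status[(minor > 0) & (minor < min_variant_reads)] = 2
    status[depth < min_depth] = 1
    maf = np.full(depth.shape, np.nan)
    ok = status == 0
    maf[ok] = minor[ok] / depth[ok]
    return maf, status


MAF_STATUS_CODES = {0: "ok", 1: "low_depth", 2: "singleton_variant", 3: "monomorphic"}


@dataclass
class SiteRecord:
    """One ascertained variant record: position, alleles, quality, genotypes.

    ``genotypes`` are per-sample derived-allele dosages (0/1/2, -1 missing);
    ``pool_counts`` holds per-pool read counts keyed by pool sample name.
    """

    scaffold: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float
    is_indel: bool
    genotypes: np.ndarray | None = None
    pool_counts: dict[str, AlleleCounts] = field(default_factory=dict)

    @property
    def is_biallelic_snp(self) -> bool:
        return (
            not self.is_indel
            and len(self.alts) == 1
            and len(self.ref) == 1
            and len(self.alts[0]) == 1
        )


def filter_variants(
    records: Iterable[SiteRecord],
    max_qual: float = MAX_QUAL,
    indel_margin: int = INDEL_MARGIN,
) -> Iterator[SiteRecord]:
    """Retain biallelic SNPs at capped quality away from called indels.

    A SNP is retained when its quality equals ``max_qual`` (the caller's cap)
    and its position differs by more than ``indel_margin`` from every called
    indel on the same scaffold (indel anchor position, either direction).
    Indel records themselves are never retained. Input must be sorted by
    (scaffold, pos); a proximity filter cannot be applied to unsorted input.
    """
    records = list(records)
    order_key = [(r.scaffold, r.pos) for r in records]
    if order_key != sorted(order_key):
        raise ValueError("records must be sorted by (scaffold, pos)")

    indel_pos: dict[str, list[int]] = {}
    for r in records:
        if r.is_indel:
            indel_pos.setdefault(r.scaffold, []).append(r.pos)

    for r in records:
        if not r.is_biallelic_snp:
            continue
        if r.qual != max_qual:
            continue
        positions = indel_pos.get(r.scaffold)
        if positions is not None:
            i = np.searchsorted(positions, r.pos)
            near = []
            if i > 0:
                near.append(positions[i - 1])
            if i < len(positions):
                near.append(positions[i])
            if any(abs(r.pos - p) <= indel_margin for p in near):
                continue
        yield r


def filter_mask(
    scaffolds: np.ndarray,
    positions: np.ndarray,
    quals: np.ndarray,
    is_indel: np.ndarray,
    is_biallelic_snp: np.ndarray,
    max_qual: float = MAX_QUAL,
    indel_margin: int = INDEL_MARGIN,
) -> np.ndarray:
    """Vectorised retention mask equivalent to :func:`filter_variants`.

    Arrays must be position-sorted within each scaffold. Returns a boolean
    mask over all records; retained records are biallelic SNPs at
    ``max_qual`` more than ``indel_margin`` bp from any indel anchor on the
    same scaffold.
    """
    scaffolds = np.asarray(scaffolds)
    positions = np.asarray(positions)
    keep = np.asarray(is_biallelic_snp, dtype=bool) & (np.asarray(quals) == max_qual)
    near_indel = np.zeros(len(positions), dtype=bool)
    for scaf in np.unique(scaffolds):
        on = scaffolds == scaf
        ipos = np.sort(positions[on & np.asarray(is_indel, dtype=bool)])
        if ipos.size == 0:
            continue
        pos = positions[on]
        left = np.searchsorted(ipos, pos - indel_margin, side="left")
        right = np.searchsorted(ipos, pos + indel_margin, side="right")
        near_indel[on] = right > left
    n_removed = int(np.sum(keep & near_indel))
    if n_removed:
        logger.debug("indel-proximity filter removed %d SNPs", n_removed)
    return keep & ~near_indel
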