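"""Readers for the standard input formats: VCF, count tables, lengths, genes.

VCF parsing goes through cyvcf2. Coordinates are 1-based on I/O (VCF, count
TSV) and 0-based half-open internally and in BED.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .sites import AlleleCounts, SiteRecord


@dataclass
class VariantTable:
    """Array-backed container for a multisample variant file.

    ``genotypes`` is (n_sites, n_samples) derived-allele dosage with -1 for
    missing; ``pool_ad`` maps each pool sample to its (ref, alt) read-count
    arrays. Multiallelic records keep dosage of the first alternate and are
    flagged non-biallelic so the retention filter can drop them.
    """

    samples: list[str]
    scaffolds: np.ndarray
    positions: np.ndarray  # 1-based
    ref: np.ndarray
    alt: np.ndarray
    quals: np.ndarray
    is_indel: np.ndarray
    is_biallelic_snp: np.ndarray
    genotypes: np.ndarray
    pool_ad: dict[str, tuple[np.ndarray, np.ndarray]]

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(
            samples=self.samples,
            scaffolds=self.scaffolds[mask],
            positions=self.positions[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            quals=self.quals[mask],
            is_indel=self.is_indel[mask],
            is_biallelic_snp=self.is_biallelic_snp[mask],
            genotypes=self.genotypes[mask],
            pool_ad={k: (r[mask], a[mask]) for k, (r, a) in self.pool_ad.items()},
        )

    def site_records(self) -> list[SiteRecord]:
        """Scalar SiteRecord view (reference representation for the filters)."""
        out = []
        for i in range(self.n_sites):
            pool_counts = {}
            for name, (r, a) in self.pool_ad.items():
                counts = {}
                if r[i] > 0:
                    counts[str(self.ref[i])] = int(r[i])
                if a[i] > 0:
                    counts[str(self.alt[i]).split(",")[0]] = int(a[i])
                if counts:
                    pool_counts[name] = AlleleCounts(
                        str(self.scaffolds[i]), int(self.positions[i]), counts
                    )
            out.append(
                SiteRecord(
                    scaffold=str(self.scaffolds[i]),
                    pos=int(self.positions[i]),
                    ref=str(self.ref[i]),
                    alts=tuple(str(self.alt[i]).split(",")),
                    qual=float(self.quals[i]),
                    is_indel=bool(self.is_indel[i]),
                    genotypes=self.genotypes[i],
                    pool_counts=pool_counts,
                )
            )
        return out


def read_vcf(path: str | Path, pool_samples: Sequence[str] = ()) -> VariantTable:
    """Read a (plain or bgzipped) VCF into a :class:`VariantTable`.

    ``pool_samples`` names the samples whose AD field carries pooled read
    counts; their per-site (ref, alt) depths are extracted alongside the
    genotype matrix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing_pools = [p for p in pool_samples if p not in samples]
    if missing_pools:
        raise ValueError(f"pool samples not in VCF: {missing_pools}")
    pool_idx = {p: samples.index(p) for p in pool_samples}

    scafs, pos, ref, alt, quals, indel, bisnp, gts = [], [], [], [], [], [], [], []
    pool_ref = {p: [] for p in pool_samples}
    pool_alt = {p: [] for p in pool_samples}
    for v in vcf:
        scafs.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(",".join(v.ALT) if v.ALT else ".")
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        indel.append(v.is_indel)
        bisnp.append(v.is_snp and len(v.ALT) == 1)
        # gt_types: 0 hom-ref, 1 het, 2 hom-alt (cyvcf2 gt_types uses 3 for hom-alt)
        g = np.asarray(v.gt_types, dtype=np.int8)
        dosage = np.select([g == 0, g == 1, g == 3], [0, 1, 2], default=-1)
        gts.append(dosage.astype(np.int8))
        if pool_samples:
            ad = v.format("AD")
            for p, j in pool_idx.items():
                if ad is None:
                    pool_ref[p].append(0)
                    pool_alt[p].append(0)
                else:
                    row = ad[j]
                    pool_ref[p].append(max(int(row[0]), 0))
                    pool_alt[p].append(max(int(row[1]), 0) if len(row) > 1 else 0)
    return VariantTable(
        samples=samples,
        scaffolds=np.array(scafs, dtype=object),
        positions=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        quals=np.array(quals, dtype=float),
        is_indel=np.array(indel, dtype=bool),
        is_biallelic_snp=np.array(bisnp, dtype=bool),
        genotypes=np.array(gts, dtype=np.int8) if gts else np.empty((0, len(samples)), np.int8),
        pool_ad={
            p: (np.array(pool_ref[p], dtype=np.int64), np.array(pool_alt[p], dtype=np.int64))
            for p in pool_samples
        },
    )


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Per-site pooled allele-count table.

    Columns: scaffold, pos (1-based), ref, alt, refCount, altCount.
    """
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "ref": str, "alt": str})
    required = {"scaffold", "pos", "ref", "alt", "refCount", "altCount"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return df


def read_scaffold_lengths(path: str | Path) -> dict[str, int]:
    """Scaffold lengths from a two-column TSV (fai columns 1-2 compatible)."""
    lengths: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        lengths[parts[0]] = int(parts[1])
    if not lengths:
        raise ValueError(f"no scaffolds in {path}")
    return lengths


def read_genes(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Gene intervals from BED (0-based half-open) or GFF3 (gene features).

    Returns (scaffold, start, end, gene_id) tuples, 0-based half-open.
    """
    path = Path(path)
    genes: list[tuple[str, int, int, str]] = []
    if path.suffix.lower() in {".gff", ".gff3"}:
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}")
            genes.append((f[0], int(f[3]) - 1, int(f[4]), gid))
    else:
        for i, line in enumerate(path.read_text().splitlines()):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            gid = f[3] if len(f) > 3 else f"gene_{i + 1}"
            genes.append((f[0], int(f[1]), int(f[2]), gid))
    return genes


def read_truth_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Truth-region BED with the region type in column 4."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        out.append((f[0], int(f[1]), int(f[2]), f[3]))
    return out
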