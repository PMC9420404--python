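"""Identity-by-state distances, neighbor joining, and site-bootstrap support.

Samples (individuals plus pools coded as pseudodiploids) are compared at
biallelic SNPs via identity by state: at one site two diploid genotypes with
dosages d_i, d_j share IBS = (2 - |d_i - d_j|) / 2 of their alleles, and the
pairwise distance is one minus the mean IBS over the sites where both are
called (pairwise-complete handling of missing data). Neighbor joining on
that distance matrix yields an unrooted tree; resampling sites with
replacement and recomputing the tree gives bootstrap support for each
internal split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sites import MIN_DEPTH, MIN_VARIANT_READS


def encode_pseudodiploid(
    ref_count: int,
    alt_count: int,
    min_depth: int = MIN_DEPTH,
    min_variant_reads: int = MIN_VARIANT_READS,
) -> int:
    """Code one pool site as a single diploid dosage (0/1/2, -1 missing).

    A pool segregating for both alleles (each supported by at least
    ``min_variant_reads`` reads) becomes a heterozygote; otherwise the pool
    is coded homozygous for its majority allele (ref on an exact tie). Sites
    below ``min_depth`` total reads are missing.
    """
    depth = ref_count + alt_count
    if depth < min_depth:
        return -1
    if ref_count >= min_variant_reads and alt_count >= min_variant_reads:
        return 1
    return 0 if ref_count >= alt_count else 2


def encode_pseudodiploid_array(
    ref_counts: np.ndarray,
    alt_counts: np.ndarray,
    min_depth: int = MIN_DEPTH,
    min_variant_reads: int = MIN_VARIANT_READS,
) -> np.ndarray:
    """Vectorised :func:`encode_pseudodiploid` over count arrays."""
    ref = np.asarray(ref_counts, dtype=np.int64)
    alt = np.asarray(alt_counts, dtype=np.int64)
    out = np.where(ref >= alt, 0, 2)
    out = np.where((ref >= min_variant_reads) & (alt >= min_variant_reads), 1, out)
    out = np.where(ref + alt < min_depth, -1, out)
    return out.astype(np.int8)


@dataclass
class DistanceMatrix:
    """Symmetric 1 - mean-IBS distances with per-pair comparable-site counts."""

    labels: list[str]
    values: np.ndarray
    n_sites: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        self.values = v

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{x:.8g}" for x in row) + "\n")


def ibs_distance_matrix(
    dosages: np.ndarray,
    labels: Sequence[str],
) -> DistanceMatrix:
    """Pairwise 1 - mean-IBS over a samples x sites dosage matrix.

    ``dosages`` holds derived-allele dosages 0/1/2 with -1 for missing; each
    pair is compared over the sites where both samples are called. A pair
    with no comparable site has no defined distance and raises.
    """
    g = np.asarray(dosages)
    n = g.shape[0]
    if n < 2:
        raise ValueError("need >= 2 samples")
    if len(labels) != n:
        raise ValueError("labels do not match matrix")
    called = g >= 0
    dist = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(f"no comparable sites for pair ({labels[i]}, {labels[j]})")
            ibs = 1.0 - np.abs(g[i, both] - g[j, both]) / 2.0
            dist[i, j] = dist[j, i] = 1.0 - ibs.mean()
            counts[i, j] = counts[j, i] = m
    np.fill_diagonal(counts, called.sum(axis=1))
    return DistanceMatrix(list(labels), dist, counts)


@dataclass
class TreeNode:
    """A node of an unrooted tree stored in rooted form; branch length is
    the length of the edge to the parent."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]


@dataclass
class Tree:
    """Unrooted binary tree with branch lengths and optional split supports."""

    root: TreeNode
    supports: dict[frozenset, float] | None = None

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def splits(self) -> set[frozenset]:
        """Non-trivial unrooted bipartitions, each canonicalised to the side
        not containing the lexicographically first leaf."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out: set[frozenset] = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(ch) for ch in node.children))
            side = all_leaves - below if ref in below else below
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
            return below

        walk(self.root)
        return out

    def newick(self, with_supports: bool = True, precision: int = 8) -> str:
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)

        def fmt(node: TreeNode, top: bool) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.{precision}g}"
            inner = ",".join(fmt(ch, False) for ch in node.children)
            label = ""
            if with_supports and self.supports is not None and not top:
                below = frozenset(node.leaf_names())
                side = all_leaves - below if ref in below else below
                if side in self.supports:
                    label = f"{self.supports[side]:g}"
            if top:
                return f"({inner}){label};"
            return f"({inner}){label}:{node.length:.{precision}g}"

        return fmt(self.root, True)

    def path_distances(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path-length matrix (for additivity checks)."""
        leaves = self.root.leaves()
        names = [l.name for l in leaves]
        idx = {id(l): i for i, l in enumerate(leaves)}
        n = len(leaves)
        dist = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[int, float]:
            if node.is_leaf:
                return {idx[id(node)]: 0.0}
            below: dict[int, float] = {}
            child_maps = []
            for ch in node.children:
                m = {k: v + ch.length for k, v in walk(ch).items()}
                child_maps.append(m)
            for i, mi in enumerate(child_maps):
                for mj in child_maps[i + 1 :]:
                    for ki, di in mi.items():
                        for kj, dj in mj.items():
                            dist[ki, kj] = dist[kj, ki] = di + dj
                below.update(mi)
            for m in child_maps[1:]:
                below.update(m)
            return below

        walk(self.root)
        return names, dist


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Neighbor joining (Studier–Keppler O(n^3) form) on an IBS distance matrix.

    Agglomerates the pair minimising the Q-criterion until three nodes
    remain, then resolves the final star exactly. On an additive matrix the
    returned tree's path distances reproduce the input. Negative branch
    length estimates are clamped to zero on output. Ties in Q are broken by
    the smallest index pair, making the construction deterministic.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need >= 3 taxa for neighbor joining")
    D = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    active = list(range(n))

    def clamp(x: float) -> float:
        return x if x > 0 else 0.0

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        ai, aj = active[i_], active[j_]
        dij = D[ai, aj]
        li = dij / 2.0 + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        nodes[ai].length = clamp(li)
        nodes[aj].length = clamp(lj)
        parent.children = [nodes[ai], nodes[aj]]
        # reuse slot ai for the new node; distances via the reduction formula
        for k in active:
            if k in (ai, aj):
                continue
            D[ai, k] = D[k, ai] = (D[ai, k] + D[aj, k] - dij) / 2.0
        nodes[ai] = parent
        active.remove(aj)

    # resolve the final three nodes with the exact three-point formulas
    x, y, z = active
    dxy, dxz, dyz = D[x, y], D[x, z], D[y, z]
    nodes[x].length = clamp((dxy + dxz - dyz) / 2.0)
    nodes[y].length = clamp((dxy + dyz - dxz) / 2.0)
    nodes[z].length = clamp((dxz + dyz - dxy) / 2.0)
    root = TreeNode(children=[nodes[x], nodes[y], nodes[z]])
    return Tree(root)


def bootstrap_support(
    dosages: np.ndarray,
    labels: Sequence[str],
    n_reps: int = 100,
    seed: int = 0,
) -> Tree:
    """Reference NJ tree with site-bootstrap support on each internal split.

    Sites (columns) are resampled with replacement ``n_reps`` times; the
    IBS + NJ construction is repeated on each replicate and each internal
    bipartition of the reference tree is scored by the percentage of
    replicate trees containing it. Deterministic for a fixed seed.
    """
    g = np.asarray(dosages)
    ref_tree = neighbor_joining(ibs_distance_matrix(g, labels))
    ref_splits = ref_tree.splits()
    counts = {s: 0 for s in ref_splits}
    rng = np.random.default_rng(seed)
    n_sites = g.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, n_sites, size=n_sites)
        rep = neighbor_joining(ibs_distance_matrix(g[:, cols], labels))
        for s in rep.splits():
            if s in counts:
                counts[s] += 1
    ref_tree.supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    return ref_tree
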