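"""IBS distances, neighbor joining, and bootstrap supports."""

import numpy as np
import pytest

from poolscan.phylo import (
    DistanceMatrix,
    bootstrap_support,
    encode_pseudodiploid,
    encode_pseudodiploid_array,
    ibs_distance_matrix,
    neighbor_joining,
)
from poolscan.simulate import SimConfig, simulate_dataset

from oracles import additive_distances


class TestPseudodiploid:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            (10, 10, 1),  # both alleles well supported -> het
            (30, 0, 0),
            (0, 30, 2),
            (30, 1, 0),  # singleton variant treated as absent
            (1, 30, 2),
            (12, 4, 1),
            (14, 2, 1),  # minor reads exactly at the variant-read threshold
            (5, 5, -1),  # depth 10 < 15 -> missing
        ],
    )
    def test_coding(self, ref, alt, expected):
        assert encode_pseudodiploid(ref, alt) == expected

    def test_array_matches_scalar(self, rng):
        ref = rng.integers(0, 40, 300)
        alt = rng.integers(0, 40, 300)
        arr = encode_pseudodiploid_array(ref, alt)
        assert all(arr[i] == encode_pseudodiploid(int(ref[i]), int(alt[i])) for i in range(300))


class TestIBSDistance:
    def test_identity_and_maximal_difference(self):
        g = np.array([[0, 1, 2], [0, 1, 2], [2, 1, 0]])
        dm = ibs_distance_matrix(g, ["a", "b", "c"])
        assert dm.values[0, 1] == 0.0
        assert dm.values[0, 2] == pytest.approx((1 + 0 + 1) / 3)

    def test_hand_enumerated_example(self):
        # sites: (0 vs 1) -> IBS 0.5; (2 vs 2) -> IBS 1 => distance 0.25
        g = np.array([[0, 2], [1, 2]])
        dm = ibs_distance_matrix(g, ["a", "b"])
        assert dm.values[0, 1] == pytest.approx(0.25)

    def test_pairwise_complete_missing_handling(self):
        g = np.array([[0, -1, 2, 1], [0, 1, -1, 1]])
        dm = ibs_distance_matrix(g, ["a", "b"])
        assert dm.n_sites[0, 1] == 2  # only sites 0 and 3 comparable
        assert dm.values[0, 1] == 0.0

    def test_no_comparable_sites_errors(self):
        g = np.array([[0, -1], [-1, 0]])
        with pytest.raises(ValueError, match="no comparable sites"):
            ibs_distance_matrix(g, ["a", "b"])

    def test_matrix_invariants_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [0.5, 0.0]]), np.ones((2, 2)))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, -0.1], [-0.1, 0.0]]), np.ones((2, 2)))


def dm_from_additive(tree):
    names, m = additive_distances(tree)
    return DistanceMatrix(names, m, np.ones_like(m, dtype=np.int64))


class TestNeighborJoining:
    def test_four_taxon_additive_inversion(self):
        """NJ reproduces the planted ((A,B),(C,D)) tree and its distances."""
        planted = (
            (
                ((("A", 1.0), ("B", 2.0)), 1.0),
                ((("C", 3.0), ("D", 4.0)), 0.0),
            ),
            0.0,
        )
        dm = dm_from_additive(planted)
        tree = neighbor_joining(dm)
        assert frozenset({"C", "D"}) in tree.splits() or frozenset({"A", "B"}) in tree.splits()
        names, got = tree.path_distances()
        order = [names.index(n) for n in dm.labels]
        np.testing.assert_allclose(got[np.ix_(order, order)], dm.values, atol=1e-9)

    def test_six_taxon_additive_inversion(self, rng):
        for _ in range(10):
            bl = rng.uniform(0.1, 2.0, size=9)
            planted = (
                (
                    ((("A", bl[0]), ("B", bl[1])), bl[2]),
                    (
                        (
                            ((("C", bl[3]), ("D", bl[4])), bl[5]),
                            ((("E", bl[6]), ("F", bl[7])), bl[8]),
                        ),
                        0.0,
                    ),
                ),
                0.0,
            )
            dm = dm_from_additive(planted)
            tree = neighbor_joining(dm)
            names, got = tree.path_distances()
            order = [names.index(n) for n in dm.labels]
            np.testing.assert_allclose(got[np.ix_(order, order)], dm.values, atol=1e-9)
            assert frozenset({"C", "D"}) in tree.splits()
            assert frozenset({"E", "F"}) in tree.splits()

    def test_three_taxon_closed_form(self):
        vals = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], vals, np.ones((3, 3), int)))
        lengths = {l.name: l.length for l in tree.root.leaves()}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_equidistant_matrix_zero_internal_branches(self):
        vals = np.full((4, 4), 0.4)
        np.fill_diagonal(vals, 0.0)
        tree = neighbor_joining(DistanceMatrix(list("abcd"), vals, np.ones((4, 4), int)))
        names, got = tree.path_distances()
        off = got[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.4, atol=1e-12)

    def test_taxon_order_invariance(self, rng):
        g = rng.integers(0, 3, size=(6, 400))
        labels = list("abcdef")
        t1 = neighbor_joining(ibs_distance_matrix(g, labels))
        perm = rng.permutation(6)
        t2 = neighbor_joining(ibs_distance_matrix(g[perm], [labels[i] for i in perm]))
        assert t1.splits() == t2.splits()

    def test_agrees_with_skbio(self, rng):
        """Independent cross-check: same topology as scikit-bio's NJ."""
        skbio = pytest.importorskip("skbio")
        g = rng.integers(0, 3, size=(7, 500))
        labels = list("abcdefg")
        dm = ibs_distance_matrix(g, labels)
        ours = neighbor_joining(dm).splits()
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm.values, labels))
        all_leaves = frozenset(labels)
        ref = min(all_leaves)
        theirs = set()
        for node in sk_tree.non_tips(include_self=False):
            below = frozenset(t.name for t in node.tips())
            side = all_leaves - below if ref in below else below
            if 2 <= len(side) <= len(all_leaves) - 2:
                theirs.add(side)
        assert ours == theirs


class TestBootstrap:
    def test_planted_species_topology_fully_supported(self):
        """On strongly diverged synthetic data the planted ((A,B),(C,D))
        split earns 100% bootstrap support."""
        cfg = SimConfig(n_scaffolds=2, scaffold_length=1_200_000, species_divergence=0.1, seed=3)
        ds = simulate_dataset(cfg)
        pool = encode_pseudodiploid_array(ds.pool_ref, ds.pool_alt)
        dosages = np.column_stack([ds.genotypes, pool]).T
        assert dosages.shape[1] >= 10_000
        tree = bootstrap_support(dosages, ds.sample_names, n_reps=100, seed=3)
        assert tree.supports[frozenset({"C_1", "C_2", "D_1", "D_2"})] == 100.0

    def test_identity_resample_gives_full_support(self, rng):
        g = rng.integers(0, 3, size=(5, 1))  # one site: every resample identical
        g = np.repeat(g, 10, axis=1)
        tree = bootstrap_support(g, list("abcde"), n_reps=5, seed=0)
        assert all(v == 100.0 for v in tree.supports.values())

    def test_deterministic_under_seed(self, rng):
        g = rng.integers(0, 3, size=(6, 200))
        t1 = bootstrap_support(g, list("abcdef"), n_reps=20, seed=7)
        t2 = bootstrap_support(g, list("abcdef"), n_reps=20, seed=7)
        assert t1.newick() == t2.newick()

    def test_newick_contains_supports_and_parses(self):
        cfg = SimConfig(n_scaffolds=1, scaffold_length=200_000, species_divergence=0.15, seed=5)
        ds = simulate_dataset(cfg)
        dosages = ds.genotypes.T
        tree = bootstrap_support(dosages, ds.cfg.individual_names, n_reps=10, seed=1)
        nwk = tree.newick()
        dendropy = pytest.importorskip("dendropy")
        t = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
        assert {l.taxon.label for l in t.leaf_node_iter()} == set(ds.cfg.individual_names)
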