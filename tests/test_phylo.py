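import math

import numpy as np
import pytest
import skbio

from ervscape import phylo
from oracles import least_squares_topology, random_additive_matrix


class TestPairwiseIdentity:
    def test_identical(self):
        assert phylo.pairwise_identity("MKVL", "MKVL") == 1.0

    def test_fully_different(self):
        assert phylo.pairwise_identity("MKVL", "ARST") == 0.0

    def test_hand_counted_toy_alignment(self):
        a = "MKV-LAXWQRTS"
        b = "MRV-LAAW-RTA"
        # 9 comparable columns (gap x2, X x1 skipped), 7 identical
        assert phylo.pairwise_identity(a, b) == pytest.approx(7 / 9)

    def test_nt_level_skips_n(self):
        assert phylo.pairwise_identity("ACGN", "ACTN", level="nt") == \
            pytest.approx(2 / 3)

    def test_no_comparable_columns_undefined(self):
        assert math.isnan(phylo.pairwise_identity("--X", "AC-"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            phylo.pairwise_identity("AC", "ACG")

    def test_identity_table_upper_nt_lower_aa(self):
        nt = {"s1": "ACGTAC", "s2": "ACGTAA"}
        aa = {"s1": "MK", "s2": "ML"}
        df = phylo.identity_table(nt, aa)
        assert df.loc["s1", "s2"] == pytest.approx(5 / 6)  # nt upper
        assert df.loc["s2", "s1"] == pytest.approx(1 / 2)  # aa lower
        assert df.loc["s1", "s1"] == 1.0


class TestKimuraDistance:
    def test_zero(self):
        assert phylo.kimura_aa_distance(0.0) == 0.0

    def test_point_one(self):
        assert phylo.kimura_aa_distance(0.1) == pytest.approx(
            -math.log(1 - 0.1 - 0.2 * 0.01)
        )

    def test_strictly_increasing_and_above_p(self):
        grid = np.linspace(0.0, 0.75, 40)
        vals = [phylo.kimura_aa_distance(p) for p in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(d >= p for d, p in zip(vals, grid))

    def test_saturation(self):
        assert math.isinf(phylo.kimura_aa_distance(0.9))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            phylo.kimura_aa_distance(-0.1)

    def test_matrix_caps_saturated_pairs(self):
        msa = {"a": "MMMM", "b": "MMMM", "c": "WWWW"}
        dm = phylo.kimura_distance_matrix(msa, saturation_distance=10.0)
        assert dm[("a", "c")] == 10.0 and dm[("a", "b")] == 0.0


class TestDistanceMatrixType:
    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            phylo.DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            phylo.DistanceMatrix(["a", "b"], np.array([[1, 1], [1, 0]]))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = phylo.DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]),
        )
        tree = phylo.nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        m = np.array(
            [
                [0.0, 5.0, 9.0, 9.0],
                [5.0, 0.0, 10.0, 10.0],
                [9.0, 10.0, 0.0, 8.0],
                [10.0, 10.0, 8.0, 0.0],
            ]
        )
        m[0, 3] = m[3, 0] = 9.0
        dm = phylo.DistanceMatrix(["a", "b", "c", "d"], m)
        tree = phylo.nj_tree(dm)
        assert phylo.bipartitions(tree) == {frozenset({"c", "d"})}
        tt = tree.tip_tip_distances(["a", "b", "c", "d"])
        np.testing.assert_allclose(tt.data, m, atol=1e-9)

    def test_six_taxon_additive_recovery(self, rng):
        labels = [f"t{i}" for i in range(6)]
        for _ in range(10):
            m, true_splits = random_additive_matrix(rng, labels)
            tree = phylo.nj_tree(phylo.DistanceMatrix(labels, m))
            assert phylo.bipartitions(tree) == true_splits
            tt = tree.tip_tip_distances(labels)
            np.testing.assert_allclose(tt.data, m, atol=1e-8)

    def test_agrees_with_skbio_on_noisy_matrices(self, rng):
        labels = [f"t{i}" for i in range(7)]
        for _ in range(10):
            m, _ = random_additive_matrix(rng, labels, noise=0.05)
            ours = phylo.nj_tree(phylo.DistanceMatrix(labels, m))
            ref = skbio.tree.nj(skbio.DistanceMatrix(m, ids=labels))
            assert phylo.bipartitions(ours) == phylo.bipartitions(ref)

    def test_agrees_with_exhaustive_least_squares_search(self, rng):
        labels = ["a", "b", "c", "d", "e"]
        for _ in range(10):
            m, _ = random_additive_matrix(rng, labels, noise=0.02)
            tree = phylo.nj_tree(phylo.DistanceMatrix(labels, m))
            assert phylo.bipartitions(tree) == least_squares_topology(m, labels)

    def test_fewer_than_three_taxa_rejected(self):
        dm = phylo.DistanceMatrix(["a", "b"], np.array([[0.0, 1], [1, 0.0]]))
        with pytest.raises(ValueError, match=">= 3"):
            phylo.nj_tree(dm)

    def test_branch_lengths_never_negative(self, rng):
        labels = [f"t{i}" for i in range(6)]
        for _ in range(10):
            m, _ = random_additive_matrix(rng, labels, noise=0.5)
            tree = phylo.nj_tree(phylo.DistanceMatrix(labels, m))
            for node in tree.traverse(include_self=False):
                assert node.length >= 0


def planted_clade_msa(rng, n_per_clade=3, length=150, p_between=0.45):
    """Two clades: near-identical within, ~p_between diverged between."""
    alpha = list("ACDEFGHIKLMNPQRSTVWY")
    base1 = rng.choice(alpha, size=length)
    base2 = base1.copy()
    flip = rng.choice(length, size=int(p_between * length), replace=False)
    for i in flip:
        base2[i] = alpha[(alpha.index(base2[i]) + 7) % 20]
    msa = {}
    for clade, base in (("A", base1), ("B", base2)):
        for k in range(n_per_clade):
            seq = base.copy()
            for i in rng.choice(length, size=3, replace=False):
                seq[i] = alpha[(alpha.index(seq[i]) + 3) % 20]
            msa[f"{clade}{k}"] = "".join(seq)
    return msa


class TestBootstrap:
    def test_planted_split_highly_supported(self, rng):
        msa = planted_clade_msa(rng)
        tree = phylo.bootstrap_support(msa, n_reps=100, seed=4)
        split = frozenset({"B0", "B1", "B2"})
        supports = {
            frozenset(
                t.name for t in node.tips()
            ): node.support
            for node in tree.non_tips(include_self=False)
            if hasattr(node, "support")
        }
        found = [
            s for clade, s in supports.items()
            if clade == split or clade == frozenset({"A0", "A1", "A2"})
        ]
        assert found and max(found) > 0.9

    def test_seed_reproducible(self, rng):
        msa = planted_clade_msa(rng)
        t1 = phylo.bootstrap_support(msa, n_reps=30, seed=9)
        t2 = phylo.bootstrap_support(msa, n_reps=30, seed=9)
        assert phylo.tree_to_newick(t1) == phylo.tree_to_newick(t2)

    def test_single_replicate_supports_are_zero_or_one(self, rng):
        msa = planted_clade_msa(rng)
        tree = phylo.bootstrap_support(msa, n_reps=1, seed=2)
        sups = [n.support for n in tree.non_tips(include_self=False)
                if hasattr(n, "support")]
        assert sups and all(s in (0.0, 1.0) for s in sups)

    def test_signal_free_alignment_has_low_support(self):
        all_sups = []
        for seed in range(4):
            rng = np.random.default_rng(1000 + seed)
            msa = {
                f"t{i}": "".join(rng.choice(list("ACDE"), size=300))
                for i in range(6)
            }
            tree = phylo.bootstrap_support(msa, n_reps=50, seed=seed)
            all_sups += [n.support for n in tree.non_tips(include_self=False)
                         if hasattr(n, "support")]
        assert np.median(all_sups) < 0.7

    def test_newick_carries_supports(self, rng):
        msa = planted_clade_msa(rng)
        nwk = phylo.tree_to_newick(
            phylo.bootstrap_support(msa, n_reps=20, seed=1)
        )
        assert nwk.endswith(";") and "0." in nwk


class TestDotMatrix:
    def test_self_comparison_diagonal(self):
        seq = "ACGTACGTGGCCTTAA"
        dm = phylo.dot_matrix(seq, seq, window=4, min_identity=1.0)
        assert np.all(np.diag(dm))

    def test_planted_duplicated_segment_off_diagonal(self, rng):
        seg = "".join(rng.choice(list("ACGT"), size=30))
        filler1 = "".join(rng.choice(list("ACGT"), size=40))
        filler2 = "".join(rng.choice(list("ACGT"), size=40))
        seq = filler1 + seg + filler2 + seg
        dm = phylo.dot_matrix(seq, seq, window=12, min_identity=1.0)
        i = 40  # first copy start; second copy at 110
        run = [dm[i + k, 110 + k] for k in range(30 - 12 + 1)]
        assert all(run)

    def test_reversal_maps_to_anti_diagonal(self):
        seq_a = "ACGGTTACGA"
        seq_b = "TTGACCAGTC"
        fwd = phylo.dot_matrix(seq_a, seq_b, window=1, min_identity=1.0)
        rev = phylo.dot_matrix(seq_a, seq_b[::-1], window=1, min_identity=1.0)
        np.testing.assert_array_equal(fwd, rev[:, ::-1])

    def test_window_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError, match="window"):
            phylo.dot_matrix("ACG", "ACGT", window=5)

    def test_partial_identity_threshold(self):
        dm = phylo.dot_matrix("AAAA", "AAAT", window=4, min_identity=0.75)
        assert dm[0, 0]
        dm_strict = phylo.dot_matrix("AAAA", "AAAT", window=4, min_identity=1.0)
        assert not dm_strict[0, 0]
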