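import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skyground import ground_metrics as gm
from skyground import trees

from .conftest import make_tree
from . import oracles


class TestRelativeAbundance:
    def test_percent_cover_to_proportions(self):
        av = gm.relative_abundance({"a": 50, "b": 30, "c": 20})
        assert np.allclose(av.p, [0.5, 0.3, 0.2])

    def test_single_species_and_uniform(self):
        assert gm.relative_abundance({"a": 7.0}).p[0] == 1.0
        av = gm.relative_abundance({"a": 5, "b": 5, "c": 5, "d": 5})
        assert np.allclose(av.p, 0.25)

    def test_zero_cover_dropped_and_empty_errors(self):
        av = gm.relative_abundance({"a": 1.0, "b": 0.0})
        assert av.species == ("a",)
        with pytest.raises(ValueError):
            gm.relative_abundance({"a": 0.0})


class TestTaxonomic:
    @pytest.mark.parametrize(
        "p, expect",
        [
            ((1.0,), {"S": 1, "H": 0.0, "D": 0.0}),
            ((0.25,) * 4, {"S": 4, "H": math.log(4), "D": 0.75}),
            ((0.5, 0.3, 0.2), {"S": 3, "H": oracles.shannon((0.5, 0.3, 0.2)),
                               "D": oracles.simpson((0.5, 0.3, 0.2))}),
        ],
    )
    def test_closed_forms(self, p, expect):
        species = tuple(f"s{i}" for i in range(len(p)))
        got = gm.taxonomic_metrics(gm.AbundanceVector(species, np.array(p)))
        for k, v in expect.items():
            assert got[k] == pytest.approx(v, abs=1e-12)

    def test_shannon_maximal_iff_uniform(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.ones(5))
            h = gm.taxonomic_metrics(gm.AbundanceVector(tuple("abcde"), p))["H"]
            assert h <= math.log(5) + 1e-12


class TestMeanPairwiseDistance:
    def test_two_members_and_constant(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        assert gm.mean_pairwise_distance(D) == 3.0
        D = np.full((4, 4), 2.5)
        np.fill_diagonal(D, 0)
        assert gm.mean_pairwise_distance(D) == 2.5

    def test_three_species_brute(self):
        D = np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], dtype=float)
        assert gm.mean_pairwise_distance(D) == pytest.approx(4.0)
        assert gm.mean_pairwise_distance(D) == pytest.approx(
            oracles.mpd_brute(D.tolist(), [0, 1, 2])
        )

    def test_single_member_is_missing_not_zero(self):
        assert math.isnan(gm.mean_pairwise_distance(np.zeros((1, 1))))


class TestFaithPD:
    def test_pair_tree(self):
        t = make_tree("(A:1,B:1);")
        assert gm.faith_pd(t, {"A", "B"}) == pytest.approx(2.0)

    def test_toy4_subsets(self, toy4_tree):
        assert gm.faith_pd(toy4_tree, {"A", "C"}) == pytest.approx(4.0)
        assert gm.faith_pd(toy4_tree, {"A", "B", "C", "D"}) == pytest.approx(
            trees.total_branch_length(toy4_tree)
        )
        # rooted convention: single member = root-to-tip path
        assert gm.faith_pd(toy4_tree, {"A"}) == pytest.approx(2.0)

    def test_unknown_member_named(self, toy4_tree):
        with pytest.raises(KeyError, match="nope"):
            gm.faith_pd(toy4_tree, {"A", "nope"})

    def test_matches_path_union_oracle(self, pool_tree):
        rng = np.random.default_rng(3)
        tips = trees.tip_labels(pool_tree)
        for _ in range(10):
            members = set(rng.choice(tips, size=5, replace=False))
            assert gm.faith_pd(pool_tree, members) == pytest.approx(
                oracles.faith_pd_brute(pool_tree, members), abs=1e-10
            )


class TestPatristic:
    def test_toy_examples(self, toy4_tree):
        labels, D = gm.patristic_matrix(toy4_tree)
        i = {lab: k for k, lab in enumerate(labels)}
        assert D[i["A"], i["B"]] == pytest.approx(2.0)
        assert D[i["A"], i["C"]] == pytest.approx(4.0)

    def test_ultrametric_identity_and_library_oracle(self, pool_tree):
        labels, D = gm.patristic_matrix(pool_tree)
        age = trees.root_age(pool_tree)
        # tips on opposite sides of the root sit at twice the root age
        assert D.max() == pytest.approx(2 * age, rel=1e-9)
        olab, OD = oracles.patristic_brute(pool_tree)
        order = [labels.index(l) for l in olab]
        assert np.allclose(D[np.ix_(order, order)], OD, atol=1e-9)

    def test_missing_branch_lengths_error(self):
        t = make_tree("(A:1,(B,C:1):1);")
        with pytest.raises(ValueError, match="branch length"):
            gm.patristic_matrix(t)


class TestDispersion:
    def test_hand_computed_chain(self):
        D = np.array([[0, 1, 0.5], [1, 0, 0.25], [0.5, 0.25, 0]])
        comp = gm.dispersion_qD(D, np.full(3, 1 / 3), q=0)
        assert np.allclose(comp.m_i, [0.75, 0.625, 0.375])
        assert comp.M_prime == pytest.approx(0.5833333333333334)
        assert comp.qDTM == pytest.approx(2.1666666666666665)

    @pytest.mark.parametrize("q", [0, 1, 2])
    def test_upper_bound_attained(self, q):
        S = 5
        D = 1.0 - np.eye(S)
        comp = gm.dispersion_qD(D, np.full(S, 1 / S), q=q)
        assert comp.qDTM == pytest.approx(S)

    @pytest.mark.parametrize("q", [0, 1, 2])
    def test_zero_distances_and_singleton(self, q):
        assert gm.dispersion_qD(np.zeros((4, 4)), np.full(4, 0.25), q).qDTM == pytest.approx(1.0)
        assert gm.dispersion_qD(np.zeros((1, 1)), np.ones(1), q).qDTM == 1.0

    def test_unscaled_distances_rejected(self):
        D = np.array([[0, 2.0], [2.0, 0]])
        with pytest.raises(ValueError, match="scaled"):
            gm.dispersion_qD(D, np.array([0.5, 0.5]), 0)

    @given(st.integers(2, 6), st.integers(0, 2), st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force(self, S, q, seed):
        rng = np.random.default_rng(seed)
        D = rng.random((S, S))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        p = rng.dirichlet(np.ones(S))
        got = gm.dispersion_qD(D, p, q).qDTM
        assert got == pytest.approx(oracles.dispersion_brute(D.tolist(), p.tolist(), q), abs=1e-10)

    @given(st.integers(2, 6), st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_permutation_invariance(self, S, seed):
        rng = np.random.default_rng(seed)
        D = rng.random((S, S))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        p = rng.dirichlet(np.ones(S))
        perm = rng.permutation(S)
        for q in (0, 1, 2):
            a = gm.dispersion_qD(D, p, q).qDTM
            b = gm.dispersion_qD(D[np.ix_(perm, perm)], p[perm], q).qDTM
            assert a == pytest.approx(b, abs=1e-12)

    def test_shrinking_distances_never_increases(self):
        rng = np.random.default_rng(5)
        D = rng.random((5, 5))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        p = rng.dirichlet(np.ones(5))
        for q in (0, 1, 2):
            base = gm.dispersion_qD(D, p, q).qDTM
            for c in (0.8, 0.5, 0.2):
                assert gm.dispersion_qD(c * D, p, q).qDTM <= base + 1e-12
        # and MPD scales linearly
        assert gm.mean_pairwise_distance(0.5 * D) == pytest.approx(
            0.5 * gm.mean_pairwise_distance(D)
        )


class TestSES:
    def test_arithmetic(self):
        nulls = np.random.default_rng(0).normal(4.0, 1.0, 999)
        res = gm.ses_standardize(6.0, nulls)
        manual = (6.0 - nulls.mean()) / nulls.std(ddof=1)
        assert res.z == pytest.approx(manual)
        assert gm.ses_standardize(nulls.mean(), nulls).z == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_null_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            gm.ses_standardize(1.0, np.ones(999))

    def test_label_shuffle_null_is_calibrated(self, pool_traits):
        # uniform random communities from the pool: z should look standard normal
        from skyground import phylo_traits as pt

        labels, G = pt.gower_distance(pool_traits)
        rng = np.random.default_rng(8)
        zs = []
        for i in range(120):
            S = int(rng.integers(3, 10))
            members = rng.choice(labels, size=S, replace=False)
            zs.append(gm.ses_mean_pairwise(G, labels, members, n_null=299, seed=1000 + i).z)
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.25
        assert 0.75 < zs.std() < 1.25
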