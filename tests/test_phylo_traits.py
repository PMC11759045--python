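import logging

import numpy as np
import pandas as pd
import pytest

from skyground import phylo_traits as pt
from skyground import synthetic, trees

from .conftest import make_tree
from . import oracles


class TestPhyloEigenvectors:
    def test_orthogonality_and_trace_identity(self, pool_tree):
        ev = pt.compute_phylo_eigenvectors(pool_tree, n_vectors=10)
        G = ev.vectors.T @ ev.vectors
        assert np.allclose(G, np.eye(10), atol=1e-8)
        assert np.all(np.diff(ev.eigenvalues) <= 1e-9)
        # spectral identity: all eigenvalues sum to the trace of -1/2 J D^2 J
        labels, D = trees.patristic_matrix(pool_tree)
        n = len(labels)
        J = np.eye(n) - np.ones((n, n)) / n
        full = np.linalg.eigvalsh(-0.5 * J @ (D**2) @ J)
        assert full.sum() == pytest.approx(np.trace(-0.5 * J @ (D**2) @ J), rel=1e-9)

    def test_first_vector_separates_balanced_clades(self):
        t = make_tree("((A:1,B:1):3,(C:1,D:1):3);")
        ev = pt.compute_phylo_eigenvectors(t, n_vectors=2)
        v1 = dict(zip(ev.species, ev.vectors[:, 0]))
        assert np.sign(v1["A"]) == np.sign(v1["B"])
        assert np.sign(v1["C"]) == np.sign(v1["D"])
        assert np.sign(v1["A"]) != np.sign(v1["C"])

    def test_degenerate_star_errors(self):
        t = make_tree("(A:0,B:0,C:0);")
        with pytest.raises(ValueError, match="degenerate"):
            pt.compute_phylo_eigenvectors(t, 1)


class TestImputation:
    def test_complete_table_returned_unchanged(self, pool_tree, pool_traits):
        out, _ = pt.impute_traits(pool_traits, seed=0)
        pd.testing.assert_frame_equal(out, pool_traits)

    def test_observed_cells_never_altered(self, pool_tree, pool_traits):
        rng = np.random.default_rng(1)
        holes = pool_traits.copy()
        mask = rng.random(holes.shape) < 0.2
        holes = holes.mask(mask)
        ev = pt.compute_phylo_eigenvectors(pool_tree)
        out, _ = pt.impute_traits(holes, ev, seed=2)
        assert not out.isna().any().any()
        obs = ~mask
        assert np.array_equal(out.to_numpy()[obs], pool_traits.to_numpy()[obs])

    def test_single_hole_within_observed_range(self, pool_traits):
        holes = pool_traits.copy()
        holes.iloc[3, 1] = np.nan
        out, _ = pt.impute_traits(holes, seed=3, n_estimators=50)
        col = pool_traits.iloc[:, 1].drop(pool_traits.index[3])
        assert col.min() <= out.iloc[3, 1] <= col.max()

    def test_all_missing_column_named(self, pool_traits):
        holes = pool_traits.copy()
        holes["trait2"] = np.nan
        with pytest.raises(ValueError, match="trait2"):
            pt.impute_traits(holes)

    def test_phylogeny_improves_holdout_recovery(self):
        # BM traits carry phylogenetic signal: eigenvector-assisted imputation
        # should recover held-out cells and beat the trait-only imputer on
        # average across seeds
        tree = synthetic.simulate_phylogeny(80, 1.0, 0.0, seed=31)
        truth = synthetic.simulate_traits(tree, 4, seed=32)
        ev = pt.compute_phylo_eigenvectors(tree)
        rs, nrmse_with, nrmse_without = [], [], []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            mask = rng.random(truth.shape) < 0.2
            holes = truth.mask(mask)
            with_ev, _ = pt.impute_traits(holes, ev, seed=seed, n_estimators=60, max_iter=4)
            no_ev, _ = pt.impute_traits(holes, None, seed=seed, n_estimators=60, max_iter=4)
            t = truth.to_numpy()[mask]
            rs.append(np.corrcoef(t, with_ev.to_numpy()[mask])[0, 1])
            sd = truth.to_numpy().std()
            nrmse_with.append(np.sqrt(((with_ev.to_numpy()[mask] - t) ** 2).mean()) / sd)
            nrmse_without.append(np.sqrt(((no_ev.to_numpy()[mask] - t) ** 2).mean()) / sd)
        assert np.mean(rs) > 0.6
        assert np.mean(nrmse_with) <= np.mean(nrmse_without)


class TestPagelsLambda:
    def test_box_constraint_and_scale_invariance(self, pool_tree, pool_traits):
        y = pool_traits["trait0"]
        est = pt.estimate_lambda(pool_tree, y)
        assert 0.0 <= est.lam <= 1.0
        est2 = pt.estimate_lambda(pool_tree, y * 1000.0)
        assert abs(est.lam - est2.lam) < 1e-6

    def test_signal_free_traits_near_zero(self, pool_tree):
        labels = trees.tip_labels(pool_tree)
        rng = np.random.default_rng(4)
        lams = [
            pt.estimate_lambda(pool_tree, pd.Series(rng.normal(size=len(labels)), index=labels)).lam
            for _ in range(25)
        ]
        assert np.mean(lams) < 0.1

    def test_bm_traits_near_one(self, pool_tree):
        traits = synthetic.simulate_traits(pool_tree, 25, seed=41)
        lams = [pt.estimate_lambda(pool_tree, traits[c]).lam for c in traits]
        assert 0.85 <= np.mean(lams) <= 1.0

    def test_zero_variance_errors(self, pool_tree):
        labels = trees.tip_labels(pool_tree)
        with pytest.raises(ValueError, match="variance"):
            pt.estimate_lambda(pool_tree, pd.Series(1.0, index=labels))


class TestAdequacy:
    def test_bm_generating_tree_favors_bm(self):
        tree = synthetic.simulate_phylogeny(100, 1.0, 0.0, seed=51)
        res = pt.adequacy_bm_ou(tree, n_sim=40, seed=52)
        assert res.fraction_bm >= 0.7
        assert res.n_failed == 0
        # evidence ratio definition: AICW(best)/AICW(other)
        ok = np.isfinite(res.evidence_ratio)
        w = res.akaike_weight_bm[ok]
        expect = np.maximum(w, 1 - w) / np.minimum(w, 1 - w)
        assert np.allclose(res.evidence_ratio[ok], expect, rtol=1e-9)

    def test_strong_ou_traits_favor_ou(self):
        tree = synthetic.simulate_phylogeny(100, 1.0, 0.0, seed=53)
        depth = trees.root_age(tree)
        traits = synthetic.simulate_traits(tree, 40, model="OU", alpha=8.0 / depth, seed=54)
        res = pt.adequacy_bm_ou(tree, traits=traits)
        assert res.fraction_ou >= 0.7


class TestGowerDistance:
    def test_identical_and_extreme_rows(self):
        tr = pd.DataFrame({"a": [1.0, 1.0, 0.0], "b": [2.0, 2.0, 5.0]},
                          index=["s1", "s2", "s3"])
        labels, G = pt.gower_distance(tr)
        assert G[0, 1] == 0.0
        assert G[0, 2] == pytest.approx(1.0)  # opposite extremes of every trait
        assert np.allclose(G, G.T) and np.all(np.diag(G) == 0)

    def test_hand_computation(self):
        tr = pd.DataFrame({"t1": [0.0, 1.0, 2.0], "t2": [10.0, 30.0, 50.0]},
                          index=["s1", "s2", "s3"])
        # ranges (2, 40): d(s1, s2) = (0.5 + 0.5) / 2
        _, G = pt.gower_distance(tr)
        assert G[0, 1] == pytest.approx(0.5)

    def test_zero_range_trait_skipped_with_warning(self, caplog):
        tr = pd.DataFrame({"flat": [3.0, 3.0], "ok": [0.0, 1.0]}, index=["a", "b"])
        with caplog.at_level(logging.WARNING):
            _, G = pt.gower_distance(tr)
        assert "zero range" in caplog.text
        assert G[0, 1] == pytest.approx(1.0)


class TestTraitDendrogram:
    def test_root_calibration_and_pair_symmetry(self):
        labels = ["a", "b"]
        D = np.array([[0.0, 0.6], [0.6, 0.0]])
        dend = pt.build_trait_dendrogram(labels, D, root_age=7.0)
        assert trees.root_age(dend) == pytest.approx(7.0, abs=1e-9)
        depths = trees.root_to_tip_depths(dend)
        assert np.allclose(depths, 7.0)

    def test_topology_matches_hand_upgma(self):
        labels = ["a", "b", "c", "d"]
        D = np.array(
            [
                [0.0, 0.2, 0.8, 0.9],
                [0.2, 0.0, 0.7, 0.8],
                [0.8, 0.7, 0.0, 0.3],
                [0.9, 0.8, 0.3, 0.0],
            ]
        )
        merges = oracles.upgma_merge_order(D.tolist(), labels)
        assert merges[0][0] == frozenset({"a", "b"})
        assert merges[1][0] == frozenset({"c", "d"})
        dend = pt.build_trait_dendrogram(labels, D, root_age=1.0)
        clades = {
            frozenset(lf.taxon.label for lf in nd.leaf_iter())
            for nd in dend.preorder_node_iter()
            if not nd.is_leaf()
        }
        assert frozenset({"a", "b"}) in clades
        assert frozenset({"c", "d"}) in clades
        assert trees.is_ultrametric(dend, tol=1e-9)

    def test_asymmetric_input_rejected(self):
        D = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pt.build_trait_dendrogram(["a", "b"], D, 1.0)
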