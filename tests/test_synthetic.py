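import numpy as np
import pandas as pd
import pytest
from scipy import stats

from skyground import ground_metrics as gm
from skyground import phylo_traits as pt
from skyground import synthetic, trees

from .conftest import make_tree


class TestSimulatePhylogeny:
    def test_tip_count_ultrametric_and_determinism(self):
        t = synthetic.simulate_phylogeny(50, 1.0, 0.0, seed=1)
        assert len(trees.tip_labels(t)) == 50
        assert trees.is_ultrametric(t, tol=1e-8)
        t2 = synthetic.simulate_phylogeny(50, 1.0, 0.0, seed=1)
        assert trees.to_newick(t) == trees.to_newick(t2)

    def test_birth_death_equal_root_to_tip_paths(self):
        t = synthetic.simulate_phylogeny(200, 1.0, 0.5, seed=7)
        depths = trees.root_to_tip_depths(t)
        assert trees.root_age(t) > 0
        assert np.ptp(depths) < 1e-8 * depths.max()

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_phylogeny(10, 0.5, 0.5)
        with pytest.raises(ValueError):
            synthetic.simulate_phylogeny(1, 1.0, 0.0)


class TestSimulateTraits:
    def test_seed_determinism(self, pool_tree):
        a = synthetic.simulate_traits(pool_tree, 3, seed=9)
        b = synthetic.simulate_traits(pool_tree, 3, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_bm_two_tip_variance_closed_form(self):
        t = make_tree("(A:2.5,B:2.5);")
        X = synthetic.simulate_traits(t, 2000, model="BM", sigma2=1.3, seed=10)
        diff = X.loc["A"] - X.loc["B"]
        # Var(tip1 - tip2) = 2 sigma^2 t for independent root-to-tip paths
        assert diff.var() == pytest.approx(2 * 1.3 * 2.5, rel=0.12)

    def test_lambda_zero_removes_phylogenetic_structure(self, pool_tree):
        labels, D = trees.patristic_matrix(pool_tree)
        iu = np.triu_indices(len(labels), k=1)
        rs = []
        for rep in range(50):
            X = synthetic.simulate_traits(pool_tree, 1, lam=0.0, seed=500 + rep)
            x = X.iloc[:, 0].reindex(labels).to_numpy()
            dis = np.abs(x[:, None] - x[None, :])[iu]
            rs.append(stats.pearsonr(dis, D[iu])[0])
        assert abs(np.mean(rs)) < 0.05

    def test_lambda_one_bm_has_structure(self, pool_tree):
        labels, D = trees.patristic_matrix(pool_tree)
        iu = np.triu_indices(len(labels), k=1)
        rs = []
        for rep in range(20):
            X = synthetic.simulate_traits(pool_tree, 1, lam=1.0, seed=700 + rep)
            x = X.iloc[:, 0].reindex(labels).to_numpy()
            dis = np.abs(x[:, None] - x[None, :])[iu]
            rs.append(stats.pearsonr(dis, D[iu])[0])
        assert np.mean(rs) > 0.15

    def test_invalid_lambda_rejected(self, pool_tree):
        with pytest.raises(ValueError):
            synthetic.simulate_traits(pool_tree, 1, lam=1.5)


class TestAssembleCommunities:
    def _pool(self, seed=60):
        cfg = synthetic.ScenarioConfig(pool_size=60, seed=seed)
        tree = synthetic.simulate_phylogeny(60, 1.0, 0.0, seed=seed)
        traits = synthetic.simulate_traits(tree, 4, seed=seed + 1)
        lib = synthetic.build_spectral_library(traits, cfg.wavelengths, seed=seed + 2)
        return synthetic.SpeciesPool(tree, traits, lib, cfg.wavelengths, 0.05)

    def test_fixed_richness_exact(self):
        pool = self._pool()
        cfg = synthetic.ScenarioConfig(
            n_sites=2, plots_per_site=5, pool_size=60, richness_range=(10, 10), seed=3
        )
        comm, sites = synthetic.assemble_communities(pool, cfg)
        per_plot = comm[comm["percent_cover"] > 0].groupby("plot")["species"].nunique()
        assert (per_plot == 10).all()
        assert set(sites.values()) == {"site00", "site01"}

    def _mean_ses_mtd(self, phi, seed):
        pool = self._pool()
        cfg = synthetic.ScenarioConfig(
            n_sites=4, plots_per_site=15, pool_size=60, richness_range=(4, 10),
            filter_strength=phi, seed=seed,
        )
        comm, _ = synthetic.assemble_communities(pool, cfg)
        labels, G = pt.gower_distance(pool.traits)
        zs = []
        for i, (plot, grp) in enumerate(comm.groupby("plot")):
            members = grp.loc[grp["percent_cover"] > 0, "species"].tolist()
            zs.append(gm.ses_mean_pairwise(G, labels, members, n_null=299, seed=i).z)
        return float(np.mean(zs))

    def test_neutral_assembly_ses_centered(self):
        assert abs(self._mean_ses_mtd(0.0, seed=5)) < 0.2

    def test_trait_filtering_clusters(self):
        assert self._mean_ses_mtd(5.0, seed=5) < -0.5


class TestSpectralLibrary:
    def test_zero_coupling_identical_signatures(self, pool_tree, pool_traits):
        wl = synthetic.ScenarioConfig().wavelengths
        lib = synthetic.build_spectral_library(pool_traits, wl, trait_coupling=0.0, seed=1)
        sig = lib.to_numpy()
        assert np.allclose(sig, sig[0])

    def test_ndvi_above_half_everywhere(self, pool_traits):
        wl = synthetic.ScenarioConfig().wavelengths
        lib = synthetic.build_spectral_library(pool_traits, wl, trait_coupling=0.08, seed=2)
        for s in lib.index:
            assert synthetic.ndvi_of(lib.loc[s].to_numpy(), wl) > 0.5

    def test_trait_distance_orders_spectral_distance(self, pool_traits):
        wl = synthetic.ScenarioConfig().wavelengths
        lib = synthetic.build_spectral_library(pool_traits, wl, trait_coupling=0.08, seed=3)
        Z = (pool_traits - pool_traits.mean()) / pool_traits.std()
        td, sd = [], []
        arr_t, arr_s = Z.to_numpy(), lib.to_numpy()
        n = arr_t.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                td.append(np.linalg.norm(arr_t[i] - arr_t[j]))
                sd.append(np.linalg.norm(arr_s[i] - arr_s[j]))
        rho = stats.spearmanr(td, sd)[0]
        assert rho > 0.5

    def test_coupling_shape_mismatch_rejected(self, pool_traits):
        wl = synthetic.ScenarioConfig().wavelengths
        with pytest.raises(ValueError, match="trait_coupling"):
            synthetic.build_spectral_library(pool_traits, wl, trait_coupling=np.ones(7))


class TestRenderPlotCube:
    def test_single_species_noise_free_pixels_collinear(self, pool_traits):
        cfg = synthetic.ScenarioConfig(
            pixel_grid=(8, 8), soil_fraction=0.0, sensor_noise_sd=0.0, seed=4
        )
        lib = synthetic.build_spectral_library(pool_traits, cfg.wavelengths, seed=4)
        sp = lib.index[0]
        cube, truth = synthetic.render_plot_cube({sp: 50.0}, lib, cfg.wavelengths, cfg, seed=5)
        X = cube.data.reshape(-1, cube.shape[2])
        Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
        cos = Xn @ Xn[0]
        assert np.allclose(cos, 1.0, atol=1e-9)  # equal up to brightness
        assert truth["richness"] == 1

    def test_default_grid_shape(self, pool_traits):
        cfg = synthetic.ScenarioConfig(seed=6)
        lib = synthetic.build_spectral_library(pool_traits, cfg.wavelengths, seed=6)
        cover = {lib.index[0]: 30.0, lib.index[1]: 20.0}
        cube, _ = synthetic.render_plot_cube(cover, lib, cfg.wavelengths, cfg, seed=7)
        assert cube.shape == (40, 40, cfg.wavelengths.size)

    def test_soil_fraction_low_ndvi_pixels(self, pool_traits):
        cfg = synthetic.ScenarioConfig(
            pixel_grid=(30, 30), soil_fraction=0.2, sensor_noise_sd=0.0, seed=8,
            wavelength_start=450, wavelength_stop=2400, wavelength_step=10,
        )
        lib = synthetic.build_spectral_library(pool_traits, cfg.wavelengths, seed=8)
        cover = {s: 10.0 for s in lib.index[:4]}
        cube, truth = synthetic.render_plot_cube(cover, lib, cfg.wavelengths, cfg, seed=9)
        from skyground.spectral_processing import ndvi

        frac_low = float((ndvi(cube) < 0.2).mean())
        assert frac_low == pytest.approx(0.2, abs=0.05)
        assert frac_low == pytest.approx(truth["soil_mask"].mean(), abs=1e-9)

    def test_mixture_weights_sum_to_one(self, small_landscape):
        for plot, truth in small_landscape.truth.items():
            W = truth["pixel_weights"]
            veg = ~truth["soil_mask"].reshape(-1)
            assert np.allclose(W[veg].sum(axis=1), 1.0, atol=1e-9)

    def test_empty_community_rejected(self, pool_traits):
        cfg = synthetic.ScenarioConfig(seed=1)
        lib = synthetic.build_spectral_library(pool_traits, cfg.wavelengths, seed=1)
        with pytest.raises(ValueError, match="empty"):
            synthetic.render_plot_cube({}, lib, cfg.wavelengths, cfg)


class TestPoolInvariants:
    def test_pool_validates(self, small_landscape):
        small_landscape.pool.validate()
        # cover > 0 implies species present in truth record
        for plot, grp in small_landscape.community.groupby("plot"):
            present = set(grp.loc[grp["percent_cover"] > 0, "species"])
            assert present == set(small_landscape.truth[plot]["species"])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            synthetic.ScenarioConfig(richness_range=(1, 5))
        with pytest.raises(ValueError):
            synthetic.ScenarioConfig(soil_fraction=1.0)
        with pytest.raises(ValueError):
            synthetic.ScenarioConfig(filter_strength=-1)
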