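import dendropy
import numpy as np
import pandas as pd
import pytest

from skyground import synthetic, trees


def make_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")


@pytest.fixture(scope="session")
def toy4_tree():
    """((A:1,B:1):1,(C:1,D:1):1); — balanced, ultrametric, depth 2."""
    return make_tree("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def pool_tree():
    return synthetic.simulate_phylogeny(60, 1.0, 0.0, seed=11)


@pytest.fixture(scope="session")
def pool_traits(pool_tree):
    return synthetic.simulate_traits(pool_tree, 4, seed=12)


@pytest.fixture(scope="session")
def small_landscape():
    """Tiny rendered landscape shared by processing/metrics tests."""
    cfg = synthetic.ScenarioConfig(
        n_sites=2, plots_per_site=3, pool_size=30, richness_range=(3, 8),
        pixel_grid=(12, 12), soil_fraction=0.15, sensor_noise_sd=0.003,
        trait_coupling=0.08, wavelength_start=450, wavelength_stop=2400,
        wavelength_step=15, seed=21,
    )
    return synthetic.simulate_landscape(cfg)
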