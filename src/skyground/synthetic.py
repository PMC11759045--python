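"""Virtual landscapes with known ground truth.

The generator produces everything the downstream stages consume: a
birth-death species pool with traits evolved on the phylogeny, percent-cover
communities nested in sites, a trait-coupled spectral library of pure
vegetation signatures, and plot-scale hyperspectral cubes whose pixels are
cover-weighted mixtures of species spectra plus soil and sensor noise.

The defaults emulate a plot network sampled by an imaging spectrometer:
40 m x 40 m plots at 1 m pixels, 426 bands from 384 to 2509 nm at 5 nm,
communities of 2-15 species drawn from a regional pool, percent cover from
a Dirichlet.  Community assembly follows a trait-filtering model: species
are drawn with weight ``exp(-phi * z_i^2)`` where ``z_i`` standardizes the
distance of a species' first trait to a plot-level environmental optimum.
``phi = 0`` gives neutral (uniform) assembly; larger ``phi`` gives trait
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from . import trees
from ._seeds import child_seed
from .cube import PlotCube

__all__ = [
    "SpeciesPool",
    "ScenarioConfig",
    "VirtualLandscape",
    "simulate_phylogeny",
    "simulate_traits",
    "assemble_communities",
    "build_spectral_library",
    "render_plot_cube",
    "soil_spectrum",
    "simulate_landscape",
]


# --------------------------------------------------------------------------
# configuration & containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of a synthetic scenario; defaults are the study conditions."""

    n_sites: int = 10
    plots_per_site: int = 20
    pool_size: int = 100
    richness_range: tuple[int, int] = (2, 15)
    filter_strength: float = 0.0  # phi >= 0; 0 = neutral assembly
    n_traits: int = 4
    wavelength_start: float = 384.0
    wavelength_stop: float = 2512.0
    wavelength_step: float = 5.0
    pixel_grid: tuple[int, int] = (40, 40)
    soil_fraction: float = 0.1
    sensor_noise_sd: float = 0.005
    trait_coupling: float = 0.05
    within_species_cv: float = 0.05  # lognormal brightness scatter
    max_species_per_pixel: int = 3
    dirichlet_concentration: float = 1.0
    birth_rate: float = 1.0
    death_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_sites", "plots_per_site", "pool_size", "n_traits",
                     "max_species_per_pixel"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (2 <= self.richness_range[0] <= self.richness_range[1] <= self.pool_size):
            raise ValueError("richness_range must lie within [2, pool_size]")
        if self.filter_strength < 0:
            raise ValueError("filter_strength must be >= 0")
        if not (0 <= self.soil_fraction < 1):
            raise ValueError("soil_fraction must be in [0, 1)")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be >= 0")
        if self.wavelength_step <= 0 or self.wavelength_stop <= self.wavelength_start:
            raise ValueError("wavelength grid must be strictly increasing")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.wavelength_start, self.wavelength_stop, self.wavelength_step)


@dataclass(frozen=True)
class SpeciesPool:
    phylogeny: dendropy.Tree
    traits: pd.DataFrame  # species x K
    spectral_library: pd.DataFrame  # species x B mean reflectance in [0, 1]
    wavelengths: np.ndarray
    within_species_cv: float

    @property
    def species(self) -> list[str]:
        return list(self.traits.index)

    def validate(self) -> None:
        tips = set(trees.tip_labels(self.phylogeny))
        if tips != set(self.traits.index) or tips != set(self.spectral_library.index):
            raise ValueError("tree tips, trait rows and spectral rows must coincide")
        R = self.spectral_library.to_numpy()
        if R.min() < 0 or R.max() > 1:
            raise ValueError("reflectance must lie in [0, 1]")
        if not trees.is_ultrametric(self.phylogeny, tol=1e-8):
            raise ValueError("phylogeny must be ultrametric")


@dataclass
class VirtualLandscape:
    pool: SpeciesPool
    community: pd.DataFrame  # plot, site, species, percent_cover
    plot_sites: dict[str, str]
    cubes: dict[str, PlotCube]
    truth: dict[str, dict]  # per plot: richness, pixel_weights, pixel_species, soil_mask
    config: ScenarioConfig


# --------------------------------------------------------------------------
# phylogeny
# --------------------------------------------------------------------------


def simulate_phylogeny(
    n_tips: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int = 0,
    max_retries: int = 20,
) -> dendropy.Tree:
    """Rooted ultrametric birth-death tree with exactly ``n_tips`` tips.

    The simulator stops at the moment the last speciation happens, which
    leaves the youngest cherry with zero-length tip branches; an extra
    exponential waiting time (the time to the next event, during which the
    tip count is unchanged) is appended to every tip so patristic distances
    between distinct species are strictly positive.
    """
    import random as _random

    from dendropy.simulate import treesim

    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not (birth_rate > death_rate >= 0):
        raise ValueError("need birth_rate > death_rate >= 0")
    rng = _random.Random(seed)
    last_err: Exception | None = None
    for _ in range(max_retries):
        try:
            tree = treesim.birth_death_tree(
                birth_rate=birth_rate,
                death_rate=death_rate,
                num_extant_tips=n_tips,
                rng=rng,
            )
            break
        except Exception as err:  # total extinction; retry with the same stream
            last_err = err
    else:
        raise RuntimeError(f"birth-death simulation failed after {max_retries} tries") from last_err

    extra = rng.expovariate(n_tips * (birth_rate + death_rate))
    for lf in tree.leaf_node_iter():
        lf.edge.length = (lf.edge.length or 0.0) + extra
    for i, lf in enumerate(tree.leaf_node_iter()):
        lf.taxon.label = f"sp{i:03d}"
    tree.seed_node.edge.length = None
    return tree


# --------------------------------------------------------------------------
# traits
# --------------------------------------------------------------------------


def simulate_traits(
    tree: dendropy.Tree,
    n_traits: int,
    model: str = "BM",
    lam: float = 1.0,
    alpha: float = 1.0,
    sigma2: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Evolve ``n_traits`` independent continuous traits on the tree.

    ``model='BM'`` uses the shared-path-length covariance; ``model='OU'``
    the Ornstein-Uhlenbeck covariance with strength ``alpha``.  Pagel's
    ``lam`` in [0, 1] rescales the off-diagonal covariance: 0 removes all
    phylogenetic structure, 1 leaves the model untouched.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    if not trees.is_ultrametric(tree, tol=1e-6):
        raise ValueError("tree must be ultrametric")
    labels, C = trees.shared_path_matrix(tree)
    if model == "BM":
        V = sigma2 * C
    elif model == "OU":
        t = C
        d = np.diag(C)[:, None] + np.diag(C)[None, :] - 2 * C
        V = sigma2 * np.exp(-alpha * d) * (1 - np.exp(-2 * alpha * t)) / (2 * alpha)
    else:
        raise ValueError("model must be 'BM' or 'OU'")
    Vl = lam * V
    np.fill_diagonal(Vl, np.diag(V))
    L = np.linalg.cholesky(Vl + 1e-12 * np.trace(Vl) / len(labels) * np.eye(len(labels)))
    rng = np.random.default_rng(seed)
    X = L @ rng.standard_normal((len(labels), n_traits))
    return pd.DataFrame(X, index=labels, columns=[f"trait{i}" for i in range(n_traits)])


# --------------------------------------------------------------------------
# communities
# --------------------------------------------------------------------------


def assemble_communities(
    pool: SpeciesPool, config: ScenarioConfig
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Draw plot communities nested in sites.

    Each site has an environmental optimum on the standardized first-trait
    axis; plots jitter around it.  Species enter a plot with weight
    ``exp(-phi * z^2)`` (distance of their first trait to the plot optimum)
    and percent covers are Dirichlet-distributed, scaled to sum to at most
    100.
    """
    if not len(pool.species):
        raise ValueError("empty species pool")
    cfg = config
    rng = np.random.default_rng(child_seed(cfg.seed, "communities"))
    t1 = pool.traits.iloc[:, 0].to_numpy(dtype=float)
    z1 = (t1 - t1.mean()) / (t1.std() if t1.std() > 0 else 1.0)
    species = np.asarray(pool.species)
    lo, hi = cfg.richness_range
    rows = []
    plot_sites: dict[str, str] = {}
    for s in range(cfg.n_sites):
        site = f"site{s:02d}"
        site_opt = rng.normal(0.0, 1.0)
        for p in range(cfg.plots_per_site):
            plot = f"{site}_plot{p:02d}"
            plot_sites[plot] = site
            opt = site_opt + rng.normal(0.0, 0.25)
            w = np.exp(-cfg.filter_strength * (z1 - opt) ** 2)
            w = w / w.sum()
            S = int(rng.integers(lo, hi + 1))
            chosen = rng.choice(len(species), size=S, replace=False, p=w)
            cover = rng.dirichlet(np.full(S, cfg.dirichlet_concentration))
            total = rng.uniform(60.0, 95.0)
            for sp_i, c in zip(chosen, cover):
                rows.append((plot, site, species[sp_i], c * total))
    community = pd.DataFrame(rows, columns=["plot", "site", "species", "percent_cover"])
    return community, plot_sites


# --------------------------------------------------------------------------
# spectra
# --------------------------------------------------------------------------


def _vegetation_template(wl: np.ndarray) -> np.ndarray:
    """Canonical green-vegetation reflectance: chlorophyll troughs near 450
    and 680 nm, a red edge onto the NIR plateau, water troughs near 1450
    and 1940 nm, declining SWIR."""
    r = np.full(wl.shape, 0.12)
    r += 0.06 * np.exp(-0.5 * ((wl - 550) / 35.0) ** 2)  # green bump
    r += 0.38 / (1.0 + np.exp(-(wl - 715) / 14.0))  # red edge to NIR plateau
    r -= 0.05 * np.exp(-0.5 * ((wl - 450) / 30.0) ** 2)  # blue chlorophyll trough
    r -= 0.07 * np.exp(-0.5 * ((wl - 680) / 22.0) ** 2)  # red chlorophyll trough
    r -= 0.22 * np.exp(-0.5 * ((wl - 1450) / 45.0) ** 2)  # water
    r -= 0.28 * np.exp(-0.5 * ((wl - 1940) / 55.0) ** 2)  # water
    r -= np.clip((wl - 1300) / 1300.0, 0.0, None) * 0.18  # SWIR decline
    return np.clip(r, 0.02, 0.95)


def soil_spectrum(wl: np.ndarray) -> np.ndarray:
    """Bare-soil spectrum: a gentle linear ramp with NDVI below 0.2."""
    r = 0.08 + 0.25 * (wl - wl.min()) / (wl.max() - wl.min())
    return np.clip(r, 0.0, 1.0)


def ndvi_of(spectrum: np.ndarray, wl: np.ndarray) -> float:
    red = spectrum[(wl >= 660) & (wl <= 680)].mean()
    nir = spectrum[(wl >= 800) & (wl <= 860)].mean()
    return float((nir - red) / (nir + red))


def build_spectral_library(
    pool_traits: pd.DataFrame,
    wavelengths: np.ndarray,
    trait_coupling: float | np.ndarray = 0.05,
    seed: int = 0,
    n_features_per_trait: int = 3,
) -> pd.DataFrame:
    """Pure-species reflectance signatures linked to traits.

    Every species starts from the shared vegetation template; each trait
    contributes Gaussian absorption/reflection features at fixed (seeded)
    wavelength centers whose amplitudes are linear in the standardized
    trait value, so larger trait distance implies larger spectral distance.
    ``trait_coupling`` scales those amplitudes (scalar, or per-trait
    vector); 0 makes all species identical.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if not ((wl >= 660) & (wl <= 680)).any() or not ((wl >= 800) & (wl <= 860)).any():
        raise ValueError("wavelength grid must cover the red (660-680) and NIR (800-860) windows")
    K = pool_traits.shape[1]
    coupling = np.asarray(trait_coupling, dtype=float)
    if coupling.ndim == 0:
        coupling = np.full(K, float(coupling))
    if coupling.shape != (K,):
        raise ValueError(f"trait_coupling must be scalar or length-{K}")

    Z = pool_traits.to_numpy(dtype=float)
    Z = (Z - Z.mean(axis=0)) / np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1.0)

    rng = np.random.default_rng(seed)
    base = _vegetation_template(wl)
    # trait-feature bank: centers keep a margin around the red (660-680)
    # and NIR (800-860) windows that define NDVI
    candidates = wl[((wl > 500) & (wl < 615)) | ((wl > 950) & (wl < 1290)) | ((wl > 1500) & (wl < 1750))]
    if candidates.size == 0:
        candidates = wl[(wl > 500) & (wl < 615)]
    for _attempt in range(20):
        feats = np.zeros((K, wl.size))
        for k in range(K):
            for _ in range(n_features_per_trait):
                c = rng.choice(candidates)
                width = rng.uniform(15.0, 40.0)
                sign = rng.choice([-1.0, 1.0])
                feats[k] += sign * np.exp(-0.5 * ((wl - c) / width) ** 2)
        sig = base[None, :] + (Z * coupling[None, :]) @ feats
        sig = np.clip(sig, 0.005, 0.98)
        lib = pd.DataFrame(sig, index=pool_traits.index, columns=[f"{w:.0f}" for w in wl])
        bad = [s for s in lib.index if ndvi_of(lib.loc[s].to_numpy(), wl) <= 0.5]
        if not bad:
            return lib
    raise ValueError(f"signature NDVI <= 0.5 for {bad[:3]}; lower trait_coupling")


# --------------------------------------------------------------------------
# plot cubes
# --------------------------------------------------------------------------


def render_plot_cube(
    plot_cover: dict[str, float] | pd.Series,
    library: pd.DataFrame,
    wavelengths: np.ndarray,
    config: ScenarioConfig,
    seed: int = 0,
) -> tuple[PlotCube, dict]:
    """Render one plot as a pixel grid of mixed species spectra.

    A ``soil_fraction`` of pixels receive the soil ramp; each vegetation
    pixel mixes at most ``max_species_per_pixel`` species (chosen with
    probability proportional to cover, weights Dirichlet-renormalized to
    sum to one), times a lognormal within-species brightness factor, plus
    Gaussian sensor noise.  Returns the cube and a truth record with the
    per-pixel weights.
    """
    if hasattr(plot_cover, "items"):
        plot_cover = dict(plot_cover.items())
    plot_cover = {s: c for s, c in plot_cover.items() if c > 0}
    if not plot_cover:
        raise ValueError("community is empty")
    wl = np.asarray(wavelengths, dtype=float)
    rng = np.random.default_rng(seed)
    rows, cols = config.pixel_grid
    n_pix = rows * cols
    sp = list(plot_cover)
    cover = np.array([plot_cover[s] for s in sp], dtype=float)
    cover = cover / cover.sum()
    sig = library.loc[sp].to_numpy(dtype=float)

    soil = soil_spectrum(wl)
    is_soil = rng.random(n_pix) < config.soil_fraction
    m = min(config.max_species_per_pixel, len(sp))
    weights = np.zeros((n_pix, len(sp)))
    data = np.empty((n_pix, wl.size))
    for i in range(n_pix):
        if is_soil[i]:
            data[i] = soil
            continue
        pick = rng.choice(len(sp), size=m, replace=False, p=cover) if m < len(sp) else np.arange(len(sp))
        w = rng.dirichlet(np.ones(pick.size) * 2.0) * cover[pick]
        w = w / w.sum()
        weights[i, pick] = w
        bright = rng.lognormal(mean=0.0, sigma=config.within_species_cv)
        data[i] = bright * (w @ sig[pick])
    if config.sensor_noise_sd > 0:
        data = data + rng.normal(0.0, config.sensor_noise_sd, size=data.shape)
    data = np.clip(data, 0.0, 1.2)

    cube = PlotCube(data.reshape(rows, cols, wl.size), wl.copy())
    veg = ~is_soil
    truth = {
        "richness": int((weights.sum(axis=0) > 0).sum()),
        "species": sp,
        "pixel_weights": weights,
        "soil_mask": is_soil.reshape(rows, cols),
        "rendered_species": [s for s, tot in zip(sp, weights.sum(axis=0)) if tot > 0],
    }
    assert not veg.any() or np.allclose(weights[veg].sum(axis=1), 1.0, atol=1e-9)
    return cube, truth


# --------------------------------------------------------------------------
# end-to-end
# --------------------------------------------------------------------------


def make_pool(config: ScenarioConfig) -> SpeciesPool:
    tree = simulate_phylogeny(
        config.pool_size, config.birth_rate, config.death_rate,
        seed=child_seed(config.seed, "phylogeny"),
    )
    traits = simulate_traits(
        tree, config.n_traits, model="BM", seed=child_seed(config.seed, "traits")
    )
    lib = build_spectral_library(
        traits, config.wavelengths, trait_coupling=config.trait_coupling,
        seed=child_seed(config.seed, "spectral_library"),
    )
    pool = SpeciesPool(tree, traits, lib, config.wavelengths, config.within_species_cv)
    pool.validate()
    return pool


def simulate_landscape(config: ScenarioConfig, pool: SpeciesPool | None = None,
                       render: bool = True) -> VirtualLandscape:
    """Full scenario: pool, communities, and (optionally) rendered cubes."""
    if pool is None:
        pool = make_pool(config)
    community, plot_sites = assemble_communities(pool, config)
    cubes: dict[str, PlotCube] = {}
    truth: dict[str, dict] = {}
    if render:
        cube_root = child_seed(config.seed, "cubes")
        for i, (plot, grp) in enumerate(community.groupby("plot", sort=True)):
            cover = dict(zip(grp["species"], grp["percent_cover"]))
            cube, t = render_plot_cube(
                cover, pool.spectral_library, pool.wavelengths, config,
                seed=(cube_root + i) & 0x7FFFFFFF,
            )
            cubes[plot] = cube
            truth[plot] = t
    return VirtualLandscape(pool, community, plot_sites, cubes, truth, config)
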