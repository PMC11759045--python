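"""Spectral diversity metrics.

Two metric families are computed from a cleaned, vector-normalized plot
cube:

* **distance-based** — the mean spectral distance MSD (pixel analog of
  MPD), the spectral diversity SD (total branch length of a UPGMA
  dendrogram over pixels, the pixel-level analog of Faith's PD), and the
  q = 0 dispersion ``0D(SM) = 1 + (n - 1) M'`` on distances scaled to
  [0, 1];
* **spectral-species-based** — pixels are clustered into spectral species
  (cluster-number ensemble + PAM, see :mod:`skyground.cluster`) and the
  cluster proportions are fed to the taxonomic formulas, giving SS
  richness (q0), Shannon (q1) and Simpson (q2).

Distances are Euclidean on the normalized spectra by default (cosine
available).  Pixel sets larger than a cap (default 400) are subsampled
with a seeded generator before any O(n^2) work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .cluster import DEFAULT_INDICES, ClusterNumberEstimate, estimate_cluster_number, pam_cluster
from .cube import PlotCube

__all__ = [
    "SpectralDistance",
    "SpectralSpeciesResult",
    "subsample_pixels",
    "spectral_distance_matrix",
    "msd",
    "spectral_sd",
    "spectral_dispersion_q0",
    "spectral_species_metrics",
    "spectral_species",
    "plot_spectral_metrics",
]


@dataclass(frozen=True)
class SpectralDistance:
    matrix: np.ndarray
    metric: str
    pixel_ids: np.ndarray  # indices into the cube's valid-pixel list
    scaling_max: float  # divisor used when scaling to [0, 1]


@dataclass(frozen=True)
class SpectralSpeciesResult:
    chosen_k: int
    per_index_k: dict[str, int]
    mean_k: float
    labels: np.ndarray
    cluster_sizes: np.ndarray
    ss_q0: float
    ss_q1: float
    ss_q2: float


def subsample_pixels(pixels: np.ndarray, cap: int = 400, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded without-replacement subsample down to ``cap`` pixels."""
    n = pixels.shape[0]
    if n <= cap:
        return pixels, np.arange(n)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=cap, replace=False))
    return pixels[idx], idx


def spectral_distance_matrix(
    pixels_or_cube, metric: str = "euclidean", cap: int = 400, seed: int = 0
) -> SpectralDistance:
    """Pairwise distances among (subsampled) valid pixel spectra."""
    pixels = (
        pixels_or_cube.valid_pixels() if isinstance(pixels_or_cube, PlotCube) else np.asarray(pixels_or_cube, float)
    )
    if pixels.shape[0] < 2:
        raise ValueError("need at least 2 valid pixels")
    pixels, idx = subsample_pixels(pixels, cap=cap, seed=seed)
    if metric not in ("euclidean", "cosine"):
        raise ValueError("metric must be 'euclidean' or 'cosine'")
    D = squareform(pdist(pixels, metric=metric))
    return SpectralDistance(D, metric, idx, float(D.max()) if D.max() > 0 else 1.0)


def msd(dist: SpectralDistance | np.ndarray) -> float:
    """Mean spectral distance over all unordered pixel pairs."""
    D = dist.matrix if isinstance(dist, SpectralDistance) else np.asarray(dist, float)
    n = D.shape[0]
    if n < 2:
        return float("nan")
    iu = np.triu_indices(n, k=1)
    return float(D[iu].mean())


def spectral_sd(dist: SpectralDistance | np.ndarray) -> float:
    """Total branch length of the UPGMA dendrogram over pixels.

    The pixel-level analog of Faith's PD: pixels play the role of tips,
    the dendrogram the role of the phylogeny.  Identical pixels contribute
    zero branch length.
    """
    D = dist.matrix if isinstance(dist, SpectralDistance) else np.asarray(dist, float)
    n = D.shape[0]
    if n < 2:
        return 0.0
    if not D.any():
        return 0.0
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    heights = np.zeros(2 * n - 1)
    heights[n:] = Z[:, 2] / 2.0
    total = 0.0
    for m in range(Z.shape[0]):
        h = heights[n + m]
        total += (h - heights[int(Z[m, 0])]) + (h - heights[int(Z[m, 1])])
    return float(total)


def spectral_dispersion_q0(dist: SpectralDistance | np.ndarray, scaling_max: float | None = None) -> float:
    """q = 0 dispersion over pixels: ``1 + (n - 1) M'`` on scaled distances."""
    D = dist.matrix if isinstance(dist, SpectralDistance) else np.asarray(dist, float)
    if scaling_max is None:
        scaling_max = dist.scaling_max if isinstance(dist, SpectralDistance) else (D.max() or 1.0)
    n = D.shape[0]
    if n < 2:
        return 1.0
    Ds = D / scaling_max
    if Ds.max() > 1 + 1e-9:
        raise ValueError("scaled distances exceed 1; wrong scaling_max")
    iu = np.triu_indices(n, k=1)
    m_prime = float(Ds[iu].sum() * 2.0 / (n * (n - 1)))
    return 1.0 + (n - 1) * m_prime


def spectral_species_metrics(labels: np.ndarray) -> dict[str, float]:
    """Hill metrics at q = 0, 1, 2 on spectral-species proportions."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty assignment")
    _, sizes = np.unique(labels, return_counts=True)
    p = sizes / sizes.sum()
    return {
        "SS_q0": float(p.size),
        "SS_q1": float(-(p * np.log(p)).sum()),
        "SS_q2": float(1.0 - (p**2).sum()),
    }


def spectral_species(
    pixels_or_cube,
    k_range: tuple[int, int] | None = None,
    indices=DEFAULT_INDICES,
    cap: int = 400,
    seed: int = 0,
) -> SpectralSpeciesResult:
    """Cluster pixels into spectral species and score their proportions.

    The cluster count is the ensemble estimate of
    :func:`skyground.cluster.estimate_cluster_number`; the final partition
    is PAM at that k on the same distance matrix.
    """
    pixels = (
        pixels_or_cube.valid_pixels() if isinstance(pixels_or_cube, PlotCube) else np.asarray(pixels_or_cube, float)
    )
    pixels, _ = subsample_pixels(pixels, cap=cap, seed=seed)
    est = estimate_cluster_number(pixels, k_range=k_range, indices=indices, seed=seed)
    if est.chosen_k <= 1:
        labels = np.zeros(pixels.shape[0], dtype=int)
    else:
        D = squareform(pdist(pixels))
        labels = pam_cluster(D, est.chosen_k, seed=seed).labels
    _, sizes = np.unique(labels, return_counts=True)
    ss = spectral_species_metrics(labels)
    return SpectralSpeciesResult(
        chosen_k=int(sizes.size),
        per_index_k=est.per_index,
        mean_k=est.mean_k,
        labels=labels,
        cluster_sizes=sizes,
        ss_q0=ss["SS_q0"],
        ss_q1=ss["SS_q1"],
        ss_q2=ss["SS_q2"],
    )


def plot_spectral_metrics(
    cube: PlotCube,
    k_range: tuple[int, int] | None = None,
    cap: int = 400,
    seed: int = 0,
    scaling_max: float | None = None,
) -> dict[str, float]:
    """All spectral metrics for one cleaned plot cube."""
    dist = spectral_distance_matrix(cube, cap=cap, seed=seed)
    ss = spectral_species(cube, k_range=k_range, cap=cap, seed=seed)
    return {
        "MSD": msd(dist),
        "SD": spectral_sd(dist),
        "0D(SM)": spectral_dispersion_q0(dist, scaling_max=scaling_max),
        "SS_q0": ss.ss_q0,
        "SS_q1": ss.ss_q1,
        "SS_q2": ss.ss_q2,
    }
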