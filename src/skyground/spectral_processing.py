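"""Hyperspectral plot cleaning.

The cleaning pipeline mirrors standard imaging-spectroscopy practice for
vegetation plots and runs in a fixed order:

1. ``filter_bands`` — drop atmospheric water-absorption windows
   [1340, 1445] and [1790, 1955] nm (closed intervals) and all bands at
   <= 400 or >= 2450 nm.
2. ``ndvi_mask`` — mask non-vegetation pixels below an NDVI threshold
   (0.5 for high vegetation cover, 0.2 for low).
3. ``brightness_mask`` — mask shaded (and, two-sided, glinted) pixels by
   Tukey's outlier fences on mean reflectance, k = 1.5.
4. ``vector_normalize`` — scale every remaining pixel spectrum to unit
   Euclidean norm, removing residual brightness differences.

Plots whose valid-pixel fraction drops below a threshold are rejected as a
typed outcome rather than an exception.  All masks are idempotent and only
ever shrink the valid set; every applied step is appended to the cube's
provenance log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cube import PlotCube

log = logging.getLogger(__name__)

__all__ = [
    "WATER_BANDS",
    "filter_bands",
    "ndvi",
    "ndvi_mask",
    "assign_cover_class",
    "brightness_mask",
    "vector_normalize",
    "PlotRejection",
    "clean_plot_pipeline",
]

WATER_BANDS = ((1340.0, 1445.0), (1790.0, 1955.0))
NDVI_THRESHOLDS = {"high": 0.5, "low": 0.2}


def band_keep_mask(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    drop = (wl <= 400.0) | (wl >= 2450.0)
    for lo, hi in WATER_BANDS:
        drop |= (wl >= lo) & (wl <= hi)
    return ~drop


def filter_bands(cube: PlotCube) -> PlotCube:
    """Remove water-absorption and edge bands, preserving band order."""
    keep = band_keep_mask(cube.wavelengths)
    if not keep.any():
        raise ValueError("no bands remain after band filtering")
    out = PlotCube(cube.data[:, :, keep], cube.wavelengths[keep],
                   cube.mask.copy(), list(cube.log))
    out.log.append(f"filter_bands(kept={int(keep.sum())}/{keep.size})")
    return out


def ndvi(cube: PlotCube) -> np.ndarray:
    """Per-pixel NDVI from the 660-680 nm (red) and 800-860 nm (NIR) windows."""
    red = cube.band_window_mean(660.0, 680.0)
    nir = cube.band_window_mean(800.0, 860.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (nir - red) / (nir + red)
    return np.where(np.isfinite(v), v, -1.0)


def ndvi_mask(cube: PlotCube, cover_class: str = "high") -> PlotCube:
    """Mask pixels with NDVI below the cover-class threshold (kept at >=)."""
    if cover_class not in NDVI_THRESHOLDS:
        raise ValueError("cover_class must be 'high' or 'low'")
    thr = NDVI_THRESHOLDS[cover_class]
    v = ndvi(cube)
    out = cube.copy()
    out.mask &= v >= thr
    out.log.append(f"ndvi_mask(cover_class={cover_class!r}, threshold={thr})")
    return out


def assign_cover_class(cube: PlotCube, ndvi_floor: float = 0.2,
                       high_fraction: float = 0.5) -> str:
    """'high' when at least half of the pixels look vegetated (NDVI >= 0.2)."""
    v = ndvi(cube)
    return "high" if float((v >= ndvi_floor).mean()) >= high_fraction else "low"


def brightness_mask(cube: PlotCube, k: float = 1.5, two_sided: bool = True) -> PlotCube:
    """Tukey outlier fences on per-pixel mean reflectance.

    Quartiles are computed over currently-valid pixels; pixels darker than
    ``Q1 - k IQR`` (shade) or — when ``two_sided`` — brighter than
    ``Q3 + k IQR`` (glint) are masked.  Fewer than 4 valid pixels is a
    warned no-op.
    """
    out = cube.copy()
    tag = f"brightness_mask(k={k}, two_sided={two_sided}"
    if any(entry.startswith(tag) for entry in out.log):
        # idempotence: the fences were already applied to this pixel set;
        # recomputing them over the survivors would shrink the IQR and
        # mask further pixels on every pass
        return out
    if out.n_valid < 4:
        log.warning("brightness_mask: fewer than 4 valid pixels, skipping")
        out.log.append("brightness_mask(skipped: <4 valid pixels)")
        return out
    bright = out.data.mean(axis=2)
    vals = bright[out.mask]
    q1, q3 = np.percentile(vals, [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    keep = bright >= lo
    if two_sided:
        keep &= bright <= hi
    out.mask &= keep
    out.log.append(f"brightness_mask(k={k}, two_sided={two_sided}, fences=({lo:.4g},{hi:.4g}))")
    return out


def vector_normalize(cube: PlotCube) -> PlotCube:
    """Scale each valid pixel spectrum to unit Euclidean norm.

    Zero-norm pixels cannot be normalized and are masked with a warning.
    """
    out = cube.copy()
    norms = np.linalg.norm(out.data, axis=2)
    zero = (norms == 0) & out.mask
    if zero.any():
        log.warning("vector_normalize: %d zero-norm pixels masked", int(zero.sum()))
        out.mask &= ~zero
    safe = np.where(norms > 0, norms, 1.0)
    out.data = out.data / safe[:, :, None]
    out.log.append("vector_normalize")
    return out


@dataclass(frozen=True)
class PlotRejection:
    """Typed rejection outcome for plots that fail quality control."""

    reason: str
    valid_fraction: float
    log: tuple[str, ...]


def clean_plot_pipeline(
    cube: PlotCube,
    cover_class: str | None = None,
    min_valid_fraction: float = 0.25,
    tukey_k: float = 1.5,
) -> PlotCube | PlotRejection:
    """filter_bands -> ndvi_mask -> brightness_mask -> vector_normalize.

    ``cover_class=None`` assigns it from the fraction of NDVI >= 0.2
    pixels.  The plot is rejected when the surviving valid-pixel fraction
    falls below ``min_valid_fraction``.
    """
    out = filter_bands(cube)
    if cover_class is None:
        cover_class = assign_cover_class(out)
    out = ndvi_mask(out, cover_class)
    out = brightness_mask(out, k=tukey_k)
    out = vector_normalize(out)
    if out.valid_fraction < min_valid_fraction:
        return PlotRejection(
            reason=f"valid fraction {out.valid_fraction:.3f} < {min_valid_fraction}",
            valid_fraction=out.valid_fraction,
            log=tuple(out.log),
        )
    return out
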