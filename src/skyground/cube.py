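"""Plot-level hyperspectral cube container.

A :class:`PlotCube` couples a pixel grid of reflectance with its wavelength
axis, a per-pixel validity mask, and a provenance log of the filters that
produced the current state.  The mask only ever shrinks as cleaning steps
run.  Cubes round-trip through band-interleaved TIFF plus a plain-text
wavelength list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PlotCube"]


@dataclass
class PlotCube:
    data: np.ndarray  # (rows, cols, bands)
    wavelengths: np.ndarray  # (bands,), nm, strictly increasing
    mask: np.ndarray | None = None  # (rows, cols) bool, True = valid
    log: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be (rows, cols, bands)")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError("band count does not match wavelength list")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    # -- basic views -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    @property
    def valid_fraction(self) -> float:
        return float(self.mask.mean())

    def valid_pixels(self) -> np.ndarray:
        """Valid-pixel spectra as an (n_valid, bands) matrix."""
        return self.data[self.mask]

    def copy(self) -> "PlotCube":
        return PlotCube(self.data.copy(), self.wavelengths.copy(),
                        self.mask.copy(), list(self.log))

    def band_window_mean(self, lo: float, hi: float) -> np.ndarray:
        sel = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not sel.any():
            raise ValueError(f"no bands in window [{lo}, {hi}] nm")
        return self.data[:, :, sel].mean(axis=2)

    def central_crop(self, rows: int, cols: int) -> "PlotCube":
        """Centered sub-window (e.g. the inner 20 x 20 m of a 40 m plot)."""
        r0 = (self.data.shape[0] - rows) // 2
        c0 = (self.data.shape[1] - cols) // 2
        if r0 < 0 or c0 < 0:
            raise ValueError("crop larger than the cube")
        out = PlotCube(
            self.data[r0 : r0 + rows, c0 : c0 + cols].copy(),
            self.wavelengths.copy(),
            self.mask[r0 : r0 + rows, c0 : c0 + cols].copy(),
            list(self.log),
        )
        out.log.append(f"central_crop(rows={rows}, cols={cols})")
        return out

    # -- IO ----------------------------------------------------------------

    def write(self, path_prefix: str) -> None:
        """Write ``<prefix>.tif`` (band-interleaved) and ``<prefix>_wavelengths.txt``."""
        import tifffile

        tifffile.imwrite(f"{path_prefix}.tif",
                         np.moveaxis(self.data, 2, 0).astype(np.float32))
        np.savetxt(f"{path_prefix}_wavelengths.txt", self.wavelengths, fmt="%.2f")

    @classmethod
    def read(cls, path_prefix: str) -> "PlotCube":
        import tifffile

        data = np.moveaxis(tifffile.imread(f"{path_prefix}.tif"), 0, 2)
        wl = np.loadtxt(f"{path_prefix}_wavelengths.txt", dtype=float)
        return cls(np.asarray(data, dtype=float), np.atleast_1d(wl))
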