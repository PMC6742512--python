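"""File formats: hyperspectral cubes (multi-page TIFF + JSON sidecar),
concentration maps (single-page float32 TIFF), and basis spectra (CSV)."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import EmissionBasis, ScalarField, SpectralCube, WavelengthGrid

__all__ = [
    "CubeSidecar",
    "read_cube",
    "write_cube",
    "read_map",
    "write_map",
    "load_emission_basis",
]


@dataclass
class CubeSidecar:
    """JSON metadata accompanying a cube TIFF."""

    wavelengths_nm: list
    illumination: str
    exposure_ms: float
    binning: str = "1x1"
    band_width_nm: float = 10.0
    provenance: dict | None = None


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_cube(cube: SpectralCube, path, provenance: dict | None = None) -> Path:
    """Write a cube as a multi-page TIFF (page order = grid order) + sidecar.

    Data is stored as 32-bit float (lossless for float32 counts); integer
    cubes are stored with their own dtype.
    """
    path = Path(path)
    pages = np.moveaxis(cube.data, 2, 0)
    if not np.issubdtype(pages.dtype, np.integer):
        pages = pages.astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = CubeSidecar(
        wavelengths_nm=[float(x) for x in cube.grid.wavelengths_nm],
        illumination=cube.illumination,
        exposure_ms=float(cube.exposure_ms),
        band_width_nm=float(cube.grid.band_width_nm),
        provenance=provenance,
    )
    _sidecar_path(path).write_text(json.dumps(asdict(sidecar), indent=1))
    return path


def read_cube(path) -> SpectralCube:
    """Read a multi-page TIFF cube and its JSON sidecar.

    Integer data (e.g. 16-bit unsigned counts) is converted to float without
    rescaling.  Page count must match the sidecar's wavelength list.
    """
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise ValueError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    wl = meta["wavelengths_nm"]
    if pages.shape[0] != len(wl):
        raise ValueError(
            f"page/wavelength count mismatch: {pages.shape[0]} pages vs "
            f"{len(wl)} wavelengths in sidecar"
        )
    grid = WavelengthGrid(np.asarray(wl, dtype=float), meta.get("band_width_nm", 10.0))
    data = np.moveaxis(pages, 0, 2).astype(np.float64)
    return SpectralCube(data, grid, meta["illumination"], meta["exposure_ms"])


def write_map(field: ScalarField, path, units_note: str | None = None) -> Path:
    """Write a scalar map as single-page float32 TIFF; masked pixels are NaN."""
    path = Path(path)
    data = np.where(field.mask, field.values, np.nan).astype(np.float32)
    tifffile.imwrite(path, data, description=units_note or field.units)
    return path


def read_map(path, units: str = "") -> ScalarField:
    data = tifffile.imread(Path(path)).astype(np.float64)
    mask = np.isfinite(data)
    return ScalarField(np.where(mask, data, 0.0), mask, units)


def load_emission_basis(
    path=None, grid: WavelengthGrid | None = None, scale: float = 1.0
) -> EmissionBasis:
    """Load a 2-column (wavelength_nm, relative_intensity) CSV basis spectrum.

    Defaults to the packaged synthetic PpIX emission shape.  The spectrum is
    linearly resampled onto ``grid`` (default: the 600–720 nm emission grid)
    and peak-normalized; absolute units enter only through ``scale``.
    """
    grid = grid or WavelengthGrid.emission()
    if path is None:
        path = resources.files("ppixmap.data") / "ppix_emission_synthetic.csv"
    tab = pd.read_csv(path)
    if tab.shape[1] < 2:
        raise ValueError("basis CSV must have two columns with a header row")
    lam = tab.iloc[:, 0].to_numpy(float)
    val = tab.iloc[:, 1].to_numpy(float)
    if np.any(val < 0):
        raise ValueError("basis spectrum must be nonnegative")
    resampled = np.interp(grid.wavelengths_nm, lam, val, left=0.0, right=0.0)
    peak = resampled.max()
    if peak <= 0:
        raise ValueError("basis spectrum is zero on the requested grid")
    return EmissionBasis(grid, resampled / peak, scale)
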