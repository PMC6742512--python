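"""Core data containers for spectrally resolved fluorescence imaging.

The acquisition model is a hyperspectral cube (x, y, λ) captured under either
UV (405 nm, PpIX excitation) or white-light illumination, on a fixed
wavelength grid of 400–720 nm in 10-nm steps (33 bands).  Quantification
happens on the PpIX emission sub-band 600–720 nm (13 bands); the excitation
diffuse reflectance is summarized over the 430/440/450 nm bands.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WavelengthGrid",
    "SpectralCube",
    "ReflectanceField",
    "ScalarField",
    "EmissionBasis",
    "KernelField",
    "ROIPatch",
    "EMISSION_BAND_NM",
    "EXCITATION_AVG_BANDS_NM",
]

#: emission band used for PpIX quantification, inclusive
EMISSION_BAND_NM = (600.0, 720.0)
#: bands averaged to summarize the excitation-side diffuse reflectance
EXCITATION_AVG_BANDS_NM = (430.0, 440.0, 450.0)


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band centers of an LCTF-style acquisition.

    Parameters
    ----------
    wavelengths_nm:
        Strictly increasing band centers in nanometers.
    band_width_nm:
        Nominal FWHM of each band (the LCTF passband), default 10 nm.
    """

    wavelengths_nm: np.ndarray
    band_width_nm: float = 10.0

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelengths_nm must be a non-empty 1-D sequence")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", wl)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        """Full acquisition grid: 400..720 nm in 10-nm steps (33 bands)."""
        return cls(np.arange(400.0, 721.0, 10.0))

    @classmethod
    def emission(cls) -> "WavelengthGrid":
        """Emission sub-grid: 600..720 nm (13 bands)."""
        return cls(np.arange(600.0, 721.0, 10.0))

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WavelengthGrid)
            and self.band_width_nm == other.band_width_nm
            and np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
        )

    def index_of(self, nm: float) -> int:
        """Index of the band centered at ``nm``; raises if absent."""
        hits = np.nonzero(np.isclose(self.wavelengths_nm, nm))[0]
        if hits.size == 0:
            raise ValueError(f"band {nm} nm not present in grid")
        return int(hits[0])

    def indices_of(self, nms) -> np.ndarray:
        return np.array([self.index_of(nm) for nm in nms])

    def subgrid(self, lo: float, hi: float) -> tuple["WavelengthGrid", np.ndarray]:
        """Restrict to band centers in [lo, hi]; returns (grid, indices)."""
        sel = np.nonzero(
            (self.wavelengths_nm >= lo - 1e-9) & (self.wavelengths_nm <= hi + 1e-9)
        )[0]
        if sel.size == 0:
            raise ValueError(f"no bands inside [{lo}, {hi}] nm")
        return WavelengthGrid(self.wavelengths_nm[sel], self.band_width_nm), sel


def _check_stack(data: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be H x W x Lambda")
    if data.shape[2] != len(grid):
        raise ValueError(
            f"wavelength axis mismatch: data has {data.shape[2]} bands, "
            f"grid has {len(grid)}"
        )
    return data


@dataclass
class SpectralCube:
    """An (H, W, Λ) stack of nonnegative camera counts on a wavelength grid."""

    data: np.ndarray
    grid: WavelengthGrid
    illumination: str  # "uv" | "white"
    exposure_ms: float = 100.0

    def __post_init__(self):
        self.data = _check_stack(self.data, self.grid)
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("cube must have H, W >= 1")
        finite = self.data[np.isfinite(self.data)]
        if finite.size and finite.min() < 0:
            raise ValueError("cube intensities must be nonnegative")
        if self.illumination not in ("uv", "white"):
            raise ValueError(f"unknown illumination tag {self.illumination!r}")
        if not self.exposure_ms > 0:
            raise ValueError("exposure_ms must be positive")

    @property
    def shape(self):
        return self.data.shape

    def band(self, nm: float) -> np.ndarray:
        """The (H, W) image at the band centered at ``nm``."""
        return self.data[:, :, self.grid.index_of(nm)]

    def restrict(self, lo: float, hi: float) -> "SpectralCube":
        """Cube restricted to band centers in [lo, hi]."""
        sub, sel = self.grid.subgrid(lo, hi)
        return SpectralCube(self.data[:, :, sel], sub, self.illumination, self.exposure_ms)


@dataclass
class ReflectanceField:
    """Per-pixel normalized diffuse reflectance R'(λ) with a validity mask.

    Masked pixels carry NaN and are excluded from all statistics downstream.
    """

    values: np.ndarray
    mask: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self):
        self.values = _check_stack(self.values, self.grid)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape[:2]:
            raise ValueError("mask shape must match spatial axes")
        valid = self.values[self.mask]
        if valid.size and np.nanmin(valid) < 0:
            raise ValueError("reflectance must be nonnegative where mask is true")

    def restrict(self, lo: float, hi: float) -> "ReflectanceField":
        sub, sel = self.grid.subgrid(lo, hi)
        return ReflectanceField(self.values[:, :, sel], self.mask.copy(), sub)


@dataclass
class ScalarField:
    """An (H, W) scalar field (e.g. mean excitation reflectance, C in µg/ml)."""

    values: np.ndarray
    mask: np.ndarray | None = None
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("scalar field must be H x W")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("field must be finite wherever mask is true")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class EmissionBasis:
    """Unit-concentration PpIX emission spectrum on the emission sub-grid.

    ``values`` is peak-normalized (max = 1) on load; absolute µg/ml units come
    solely from ``scale``, obtained by calibrating against one known phantom.
    """

    grid: WavelengthGrid
    values: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != len(self.grid):
            raise ValueError("basis values must match grid length")
        if self.values.min() < 0:
            raise ValueError("basis spectrum must be nonnegative")
        if not np.isclose(self.values.max(), 1.0):
            raise ValueError("basis spectrum must be peak-normalized (max == 1)")
        if not self.scale > 0:
            raise ValueError("scale must be positive")


@dataclass
class KernelField:
    """Per-pixel model kernel h(λ) = (1 − R̄'_ex)[R'_em(λ)]^q f_basic(λ)."""

    values: np.ndarray
    q: float
    mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("kernel must be H x W x Lambda")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape[:2]:
            raise ValueError("mask shape must match spatial axes")
        if not np.isfinite(self.q):
            raise ValueError("q must be finite")
        valid = self.values[self.mask]
        if valid.size and np.nanmin(valid) < 0:
            raise ValueError("kernel must be nonnegative where mask is true")


@dataclass(frozen=True)
class ROIPatch:
    """Rectangular pixel patch, 0-based, half-open rows/cols."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError("patch must have height, width >= 1")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("patch origin must be nonnegative")

    @classmethod
    def centered(cls, shape, height: int, width: int) -> "ROIPatch":
        """Patch of the given size centered in an (H, W) image."""
        h, w = shape[:2]
        return cls((h - height) // 2, (w - width) // 2, height, width)

    def validate(self, shape) -> None:
        h, w = shape[:2]
        if self.row0 + self.height > h or self.col0 + self.width > w:
            raise ValueError(f"patch {self} does not fit inside image {h}x{w}")

    @property
    def slices(self):
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )

    def extract(self, arr: np.ndarray) -> np.ndarray:
        self.validate(arr.shape)
        return arr[self.slices]

    def overlaps(self, other: "ROIPatch") -> bool:
        return not (
            self.row0 + self.height <= other.row0
            or other.row0 + other.height <= self.row0
            or self.col0 + self.width <= other.col0
            or other.col0 + other.width <= self.col0
        )
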