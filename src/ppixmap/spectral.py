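"""Reflectance calibration and per-pixel PpIX quantification.

The measured fluorescence at a pixel is modeled as

    F(λ) = (1 − R̄'_ex) [R'_em(λ)]^q f_basic(λ) C + ε,   λ ∈ [600, 720] nm

where R'_ex and R'_em are the diffuse reflectances under UV and white-light
illumination normalized to a reference diffuse reflector (this normalization
absorbs the lighting and collection geometry), R̄'_ex is R'_ex averaged over
the 430/440/450 nm bands, f_basic is the unit-concentration PpIX emission
spectrum, q is an empirical calibration exponent (default 2.6), and C is the
PpIX concentration to retrieve.  With the per-pixel kernel
h(λ) = (1 − R̄'_ex)[R'_em(λ)]^q f_basic(λ), the least-squares estimate is the
exact 1-D minimizer of ‖h·C − F‖²:  C_ls = ⟨F, h⟩ / ⟨h, h⟩.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import (
    EXCITATION_AVG_BANDS_NM,
    EmissionBasis,
    KernelField,
    ROIPatch,
    ReflectanceField,
    ScalarField,
    SpectralCube,
)

__all__ = [
    "DEFAULT_Q",
    "normalize_reflectance",
    "mean_excitation_reflectance",
    "build_kernel",
    "ls_concentration",
    "corrected_spectrum",
    "valdes_correction",
    "rgb_composite",
    "calibrate_scale",
]

log = logging.getLogger(__name__)

#: default attenuation calibration exponent, determined empirically on phantoms
DEFAULT_Q = 2.6

#: upper clamp for R̄'_ex before forming (1 − R̄'_ex); normalized reflectance can
#: exceed 1 on specular pixels, which would flip the kernel sign
_RBAR_CLAMP = 1.0 - 1e-6


def normalize_reflectance(
    meas: SpectralCube, ref: SpectralCube, floor: float | None = None
) -> ReflectanceField:
    """Normalize a measured cube by a reference diffuse-reflectance cube.

    Computes ``meas / ref`` per pixel and band, after compensating any
    exposure-time difference by the ratio of exposures.  Pixels where the
    reference falls below ``floor`` at any band are masked out (the dark edge
    of the Gaussian illumination field produces exploding ratios there).

    Parameters
    ----------
    meas, ref:
        Cubes sharing grid, shape and illumination tag.
    floor:
        Reference validity threshold in counts.  Defaults to 1e-3 of the
        reference cube's global maximum.
    """
    if meas.grid != ref.grid:
        raise ValueError("grid mismatch between measurement and reference (wavelength axis)")
    if meas.shape != ref.shape:
        raise ValueError(
            f"shape mismatch on spatial axes: {meas.shape[:2]} vs {ref.shape[:2]}"
        )
    if meas.illumination != ref.illumination:
        raise ValueError(
            f"illumination-tag mismatch: {meas.illumination!r} vs {ref.illumination!r}"
        )
    if floor is None:
        floor = 1e-3 * float(ref.data.max())
    if floor < 0:
        raise ValueError("floor must be nonnegative")

    mask = np.all(ref.data >= floor, axis=2)
    exposure_gain = ref.exposure_ms / meas.exposure_ms
    with np.errstate(divide="ignore", invalid="ignore"):
        values = meas.data / ref.data * exposure_gain
    values[~mask] = np.nan
    return ReflectanceField(values, mask, meas.grid)


def mean_excitation_reflectance(rex: ReflectanceField) -> ScalarField:
    """R̄'_ex: unweighted mean of R'_ex over the 430, 440 and 450 nm bands."""
    idx = rex.grid.indices_of(EXCITATION_AVG_BANDS_NM)  # raises naming the band
    values = rex.values[:, :, idx].mean(axis=2)
    values = np.where(rex.mask, values, np.nan)
    out = np.where(rex.mask, values, 0.0)
    return ScalarField(out, rex.mask.copy(), units="")


def build_kernel(
    rbar: ScalarField,
    rem: ReflectanceField,
    basis: EmissionBasis,
    q: float = DEFAULT_Q,
) -> KernelField:
    """Per-pixel model kernel h(λ) = (1 − R̄'_ex)[R'_em(λ)]^q f_basic(λ).

    R̄'_ex is clamped into [0, 1) before use: shiny (specular) pixels can show
    normalized reflectance above 1, which would make the kernel nonpositive.
    Clamped pixels are counted and logged.  Pixels with negative R'_em under a
    non-integer ``q`` are masked (the power is undefined there).
    """
    if rem.grid != basis.grid:
        rem = rem.restrict(
            basis.grid.wavelengths_nm[0], basis.grid.wavelengths_nm[-1]
        )
        if rem.grid != basis.grid:
            raise ValueError("R'_em grid cannot be restricted to the basis grid")
    if rbar.shape != rem.values.shape[:2]:
        raise ValueError("R̄'_ex and R'_em spatial shapes differ")

    mask = rbar.mask & rem.mask
    rb = np.clip(rbar.values, 0.0, _RBAR_CLAMP)
    n_clamped = int(np.sum((rbar.values != rb) & mask))
    if n_clamped:
        log.info("build_kernel: clamped R̄'_ex on %d specular pixel(s)", n_clamped)

    rem_vals = rem.values
    if q != np.round(q):
        neg = np.any(rem_vals < 0, axis=2) & mask
        n_neg = int(neg.sum())
        if n_neg:
            log.warning(
                "build_kernel: masked %d pixel(s) with negative R'_em under "
                "non-integer q=%g", n_neg, q,
            )
            mask = mask & ~neg

    with np.errstate(invalid="ignore"):
        values = (1.0 - rb)[:, :, None] * rem_vals**q * basis.values[None, None, :]
    values[~mask] = np.nan
    return KernelField(values, float(q), mask)


def ls_concentration(
    fluo: SpectralCube,
    kernel: KernelField,
    basis_scale: float = 1.0,
    variant: str = "exact",
) -> ScalarField:
    """Per-pixel least-squares PpIX concentration estimate.

    ``variant="exact"`` returns the true minimizer of ‖h·C − F‖², i.e.
    ``C = basis_scale · ⟨F, h⟩ / ⟨h, h⟩``.  ``variant="printed"`` divides by
    ‖h‖₂ instead of ‖h‖₂², kept only for comparison with formulations that
    normalize by the kernel norm.
    """
    if basis_scale <= 0:
        raise ValueError("basis_scale must be positive")
    if variant not in ("exact", "printed"):
        raise ValueError(f"unknown variant {variant!r}")
    if fluo.data.shape != kernel.values.shape:
        raise ValueError(
            f"shape mismatch: fluorescence {fluo.data.shape} vs kernel "
            f"{kernel.values.shape}"
        )
    h = np.where(kernel.mask[:, :, None], kernel.values, 0.0)
    num = np.einsum("ijk,ijk->ij", fluo.data, h)
    den = np.einsum("ijk,ijk->ij", h, h)
    mask = kernel.mask & (den > 0)
    if not mask.any():
        raise ValueError("no valid pixels: kernel is zero everywhere")
    with np.errstate(divide="ignore", invalid="ignore"):
        if variant == "exact":
            c = basis_scale * num / den
        else:
            c = basis_scale * num / np.sqrt(den)
    c = np.where(mask, c, 0.0)
    return ScalarField(c, mask, units="ug/ml")


def corrected_spectrum(
    fluo: SpectralCube,
    rbar: ScalarField,
    rem: ReflectanceField,
    q: float = DEFAULT_Q,
) -> SpectralCube:
    """Equalized emission spectrum F(λ) / [(1 − R̄'_ex) · R'_em(λ)^q].

    Dividing out the attenuation model leaves f_basic(λ)·C, so spectra of
    phantoms sharing C but differing in absorber/scatterer content collapse
    onto each other; the per-phantom 640-nm peaks of this quantity feed the
    NRMSD equalization metric.  Bands with a zero denominator are NaN-masked
    at that pixel.
    """
    if fluo.data.shape[:2] != rbar.shape:
        raise ValueError("fluorescence and R̄'_ex spatial shapes differ")
    if rem.grid != fluo.grid:
        raise ValueError("R'_em grid must match the fluorescence grid")
    rb = np.clip(rbar.values, 0.0, _RBAR_CLAMP)
    denom = (1.0 - rb)[:, :, None] * rem.values**q
    mask3 = (rbar.mask & rem.mask)[:, :, None] & (denom > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mask3, fluo.data / denom, np.nan)
    return SpectralCube(out, fluo.grid, fluo.illumination, fluo.exposure_ms)


def valdes_correction(
    fluo: SpectralCube, refl: ReflectanceField, alpha: float
) -> SpectralCube:
    """Attenuation correction of Valdés et al.: F / (Φ_ex · Φ_em^α).

    Φ_ex and Φ_em integrate the normalized diffuse reflectance over
    λ ∈ [465, 485] nm and λ ∈ [625, 645] nm (trapezoid rule over the 460/470/
    480 and 620/630/640 band centers on the 10-nm grid).  Pixels with a
    nonpositive Φ are NaN-masked.
    """
    phi = []
    for center in (470.0, 630.0):
        idx = refl.grid.indices_of((center - 10, center, center + 10))
        band = refl.values[:, :, idx]
        phi.append(np.trapezoid(band, refl.grid.wavelengths_nm[idx], axis=2))
    phi_ex, phi_em = phi
    ok = refl.mask & (phi_ex > 0) & (phi_em > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = phi_ex * phi_em**alpha
        out = np.where(ok[:, :, None], fluo.data / denom[:, :, None], np.nan)
    return SpectralCube(out, fluo.grid, fluo.illumination, fluo.exposure_ms)


def rgb_composite(cube: SpectralCube) -> np.ndarray:
    """Qualitative RGB image from the 630 / 540 / 470 nm bands.

    All three channels share one linear rescaling (global max → 1) so the
    composite preserves relative band intensities.
    """
    channels = np.stack(
        [cube.band(nm) for nm in (630.0, 540.0, 470.0)], axis=-1
    )
    peak = float(np.nanmax(channels))
    if peak > 0:
        channels = channels / peak
    return np.clip(channels, 0.0, 1.0)


def calibrate_scale(cmap: ScalarField, roi: ROIPatch, true_c: float) -> float:
    """Amplitude→µg/ml factor from one phantom of known concentration.

    Returns ``true_c / mean(cmap over roi)`` (masked pixels excluded).
    """
    if true_c <= 0:
        raise ValueError("true_c must be positive")
    roi.validate(cmap.shape)
    vals = roi.extract(cmap.values)[roi.extract(cmap.mask)]
    if vals.size == 0:
        raise ValueError("ROI contains no valid pixels")
    m = float(vals.mean())
    if m <= 0:
        raise ValueError("nonpositive ROI mean; cannot calibrate scale")
    return true_c / m
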