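"""Image-quality and agreement metrics.

CNR = (µ_ROI − µ_background) / σ_background;
RMSE = √(Σ(X−Y)²/(M·N));
NRMSD = RMS deviation of a value set from its mean, as a % of the mean;
plus ordinary least-squares linear fits (R²) and Pearson correlation with a
two-sided t-test p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import ROIPatch, ScalarField

__all__ = ["CnrReport", "FitReport", "cnr", "rmse", "nrmsd", "linear_fit_r2", "pearson"]


@dataclass(frozen=True)
class CnrReport:
    cnr: float
    roi_mean: float
    bkg_mean: float
    bkg_std: float
    roi: ROIPatch
    bkg: ROIPatch


@dataclass(frozen=True)
class FitReport:
    slope: float
    intercept: float
    r2: float
    n: int


def _patch_values(field: ScalarField, patch: ROIPatch) -> np.ndarray:
    vals = patch.extract(field.values)[patch.extract(field.mask)]
    if vals.size == 0:
        raise ValueError("patch contains no valid pixels")
    return vals


def cnr(
    field: ScalarField, roi: ROIPatch, bkg: ROIPatch, ddof: int = 0
) -> CnrReport:
    """Contrast-to-noise ratio between an ROI patch and a background patch.

    The background standard deviation uses the population form (denominator
    N, ``ddof=0``) by default for determinism on small patches; pass
    ``ddof=1`` for the sample form.
    """
    if roi.overlaps(bkg):
        warnings.warn("ROI and background patches overlap", stacklevel=2)
    rv = _patch_values(field, roi)
    bv = _patch_values(field, bkg)
    bstd = float(bv.std(ddof=ddof))
    if bstd == 0:
        raise ValueError("CNR undefined: background has zero variance")
    rm, bm = float(rv.mean()), float(bv.mean())
    return CnrReport((rm - bm) / bstd, rm, bm, bstd, roi, bkg)


def rmse(x: ScalarField, y: ScalarField) -> float:
    """Root-mean-square error over jointly unmasked pixels."""
    if x.shape != y.shape:
        raise ValueError("shape mismatch between the two fields")
    mask = x.mask & y.mask
    if not mask.any():
        raise ValueError("no jointly valid pixels")
    d = (x.values - y.values)[mask]
    return float(np.sqrt(np.mean(d * d)))


def nrmsd(values, normalization: str = "mean") -> float:
    """Normalized RMS deviation of a value set, in percent.

    The default normalizes the RMS deviation from the mean by the mean
    (coefficient-of-variation reading); ``"range"`` and ``"max"`` variants
    are provided for comparison.  Scale-invariant, translation-sensitive.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    m = v.mean()
    rms = np.sqrt(np.mean((v - m) ** 2))
    if normalization == "mean":
        denom = m
    elif normalization == "range":
        denom = v.max() - v.min()
    elif normalization == "max":
        denom = v.max()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if denom <= 0:
        raise ValueError("nonpositive normalization denominator")
    return float(100.0 * rms / denom)


def linear_fit_r2(x, y) -> FitReport:
    """Ordinary least-squares line with intercept and its R²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; fit undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant y triggers a harmless warning
        fit = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue**2)
    return FitReport(float(fit.slope), float(fit.intercept), r2, int(x.size))


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided p (t-distribution, n−2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
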