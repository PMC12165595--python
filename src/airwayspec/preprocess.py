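"""Raw counts -> reflectance -> peak-normalized spectrum -> 2-D features.

The processing chain mirrors the acquisition protocol: reference
correction against paired dark/white spectra, normalization at the
561 nm oxyhemoglobin reflectance peak, and extraction of the normalized
reflectance at the two flanking absorption troughs (543 and 578 nm).
Wavelength lookups interpolate linearly between grid points, so results
do not depend on the spectrometer's pixel pitch.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import ANALYSIS_BAND, AcquisitionMeta, RawSpectrum, ReferenceSet

__all__ = [
    "PEAK_NM",
    "TROUGH_NM",
    "DegenerateReferenceError",
    "NormalizationError",
    "WavelengthRangeError",
    "ReflectanceSpectrum",
    "NormalizedSpectrum",
    "FeatureVector",
    "value_at_wavelength",
    "reference_correct",
    "peak_normalize",
    "extract_features",
]

PEAK_NM = 561.0
TROUGH_NM = (543.0, 578.0)


class WavelengthRangeError(ValueError):
    """Requested wavelength outside the grid, or at a flagged grid point."""


class DegenerateReferenceError(ValueError):
    """white - dark <= 0 inside the analysis band."""


class NormalizationError(ValueError):
    """Non-positive reflectance at the 561 nm normalization peak."""


@dataclasses.dataclass
class ReflectanceSpectrum:
    """Dimensionless reflectance per grid point for one acquisition.

    Grid points where the reference correction was degenerate (outside
    the analysis band only) hold NaN; looking them up raises.
    """

    grid: np.ndarray
    reflectance: np.ndarray
    meta: AcquisitionMeta


@dataclasses.dataclass
class NormalizedSpectrum:
    """Reflectance scaled so the interpolated value at 561 nm is 1."""

    grid: np.ndarray
    norm_refl: np.ndarray
    meta: AcquisitionMeta


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """Normalized reflectance at the 543 and 578 nm troughs."""

    r543: float
    r578: float
    meta: AcquisitionMeta

    def as_array(self) -> np.ndarray:
        return np.array([self.r543, self.r578], dtype=float)


def value_at_wavelength(
    grid: np.ndarray, values: np.ndarray, lam: float
) -> float:
    """Linearly interpolated value at wavelength ``lam`` (nm).

    An exact grid hit returns the stored value. Raises
    :class:`WavelengthRangeError` if ``lam`` lies outside the grid or if
    a bracketing value is non-finite (a flagged degenerate point).
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if lam < grid[0] or lam > grid[-1]:
        raise WavelengthRangeError(
            f"wavelength {lam} nm outside grid [{grid[0]}, {grid[-1]}] nm"
        )
    j = int(np.searchsorted(grid, lam))
    if j < grid.size and grid[j] == lam:
        v = values[j]
        if not np.isfinite(v):
            raise WavelengthRangeError(f"value at {lam} nm is flagged non-finite")
        return float(v)
    lo, hi = j - 1, j
    x0, x1 = grid[lo], grid[hi]
    y0, y1 = values[lo], values[hi]
    if not (np.isfinite(y0) and np.isfinite(y1)):
        raise WavelengthRangeError(
            f"interpolation at {lam} nm touches a flagged degenerate point"
        )
    t = (lam - x0) / (x1 - x0)
    return float(y0 + t * (y1 - y0))


def reference_correct(raw: RawSpectrum, refs: ReferenceSet) -> ReflectanceSpectrum:
    """Convert counts to reflectance: (raw - dark) / (white - dark).

    ``white - dark <= 0`` is fatal inside the analysis band and flagged
    (NaN) outside it, where the values never feed the analysis.
    """
    if raw.grid.shape != refs.grid.shape or not np.array_equal(raw.grid, refs.grid):
        raise ValueError("raw spectrum and references must share one grid")
    denom = refs.white - refs.dark
    lo, hi = ANALYSIS_BAND
    band = (raw.grid >= lo) & (raw.grid <= hi)
    bad = denom <= 0
    if np.any(bad & band):
        raise DegenerateReferenceError(
            "white - dark <= 0 inside the analysis band "
            f"{ANALYSIS_BAND} nm for {raw.meta}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw.counts - refs.dark) / denom
    refl = np.where(bad, np.nan, refl)
    return ReflectanceSpectrum(grid=raw.grid, reflectance=refl, meta=raw.meta)


def peak_normalize(refl: ReflectanceSpectrum) -> NormalizedSpectrum:
    """Scale so the interpolated reflectance at 561 nm equals 1."""
    peak = value_at_wavelength(refl.grid, refl.reflectance, PEAK_NM)
    if peak <= 0:
        raise NormalizationError(
            f"reflectance at {PEAK_NM} nm is {peak:g} (must be > 0) for {refl.meta}"
        )
    return NormalizedSpectrum(
        grid=refl.grid, norm_refl=refl.reflectance / peak, meta=refl.meta
    )


def extract_features(norm: NormalizedSpectrum) -> FeatureVector:
    """Normalized reflectance at the 543 and 578 nm troughs."""
    r543 = value_at_wavelength(norm.grid, norm.norm_refl, TROUGH_NM[0])
    r578 = value_at_wavelength(norm.grid, norm.norm_refl, TROUGH_NM[1])
    return FeatureVector(r543=r543, r578=r578, meta=norm.meta)


def features_from_raw(raw: RawSpectrum, refs: ReferenceSet) -> FeatureVector:
    """Full per-spectrum chain: correct, normalize, extract."""
    return extract_features(peak_normalize(reference_correct(raw, refs)))
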