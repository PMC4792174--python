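"""Isotope-envelope integration over chromatographic elution.

A simplified front end for turning MS1 spectra into per-time-point
isotopomer fractional abundances: extract an ion chromatogram within a ppm
window around each isotopomer m/z, smooth it with a Savitzky-Golay filter,
integrate trapezoidally over the elution window, and normalize the areas
so the fractions sum to one.  Isotopomer m/z spacing is one neutron mass
divided by charge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "NEUTRON_MASS",
    "SpectrumSlice",
    "IntegrationParams",
    "isotopomer_mz",
    "extract_xic",
    "smooth_trace",
    "integrate_envelope",
]

NEUTRON_MASS = 1.008665  # Da, nominal spacing between mass isotopomers


@dataclass
class SpectrumSlice:
    """One centroided MS1 scan: retention time plus (m/z, intensity) arrays."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if len(self.mz) > 1 and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")


@dataclass(frozen=True)
class IntegrationParams:
    """Envelope-integration settings: ppm window and XIC smoothing."""

    ppm: float = 60.0
    smooth_window: int = 7
    smooth_order: int = 2

    def __post_init__(self) -> None:
        if self.ppm <= 0:
            raise ValueError("ppm window must be positive")
        if self.smooth_window < 5 or self.smooth_window % 2 == 0:
            raise ValueError("smoothing window must be odd and >= 5")


def isotopomer_mz(mono_mz: float, mi: int, charge: int) -> float:
    """m/z of the mi-th isotopomer of an ion at monoisotopic m/z mono_mz."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return mono_mz + mi * NEUTRON_MASS / charge


def extract_xic(
    spectra: Sequence[SpectrumSlice],
    target_mz: float,
    params: IntegrationParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Extracted ion chromatogram within +-ppm of a target m/z.

    Per spectrum, sums the intensity of points in the half-open window
    [mz*(1-d), mz*(1+d)) with d = ppm*1e-6.  Returns (times, intensities).
    """
    if params is None:
        params = IntegrationParams()
    delta = params.ppm * 1e-6 * target_mz
    lo, hi = target_mz - delta, target_mz + delta
    times = np.array([s.rt for s in spectra], dtype=float)
    if len(times) > 1 and np.any(np.diff(times) < 0):
        raise ValueError("spectra must be sorted by retention time")
    intensities = np.array(
        [
            float(s.intensity[(s.mz >= lo) & (s.mz < hi)].sum()) if len(s.mz) else 0.0
            for s in spectra
        ]
    )
    return times, intensities


def smooth_trace(trace, params: IntegrationParams | None = None) -> np.ndarray:
    """Savitzky-Golay smoothing of an XIC trace.

    A quadratic filter preserves constant and linear traces exactly.
    Traces shorter than the window are returned unchanged with a warning.
    """
    import warnings

    if params is None:
        params = IntegrationParams()
    trace = np.asarray(trace, dtype=float)
    if len(trace) < params.smooth_window:
        warnings.warn(
            f"trace of length {len(trace)} shorter than smoothing window "
            f"{params.smooth_window}; returned unsmoothed"
        )
        return trace.copy()
    return savgol_filter(trace, params.smooth_window, params.smooth_order)


def integrate_envelope(
    spectra: Sequence[SpectrumSlice],
    isotopomer_mzs: Sequence[float],
    rt_bounds: tuple[float, float],
    params: IntegrationParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate each isotopomer XIC over an elution window.

    Parameters
    ----------
    isotopomer_mzs
        m/z of isotopomers mi = 0..n-1 (e.g. from :func:`isotopomer_mz`).
    rt_bounds
        (start, end) retention times of the elution window, supplied
        externally from the identification.

    Returns
    -------
    (areas, fractions): trapezoidal areas under the smoothed XICs and the
    same areas normalized to sum to one.

    Raises
    ------
    ValueError
        If fewer than 2 spectra fall within the window, or every
        isotopomer area is zero.
    """
    if params is None:
        params = IntegrationParams()
    lo, hi = rt_bounds
    window = [s for s in spectra if lo <= s.rt <= hi]
    if len(window) < 2:
        raise ValueError("need >= 2 spectra inside the elution window")
    areas = np.empty(len(isotopomer_mzs))
    for j, mz in enumerate(isotopomer_mzs):
        times, trace = extract_xic(window, mz, params)
        trace = smooth_trace(trace, params)
        areas[j] = np.trapezoid(np.clip(trace, 0.0, None), times)
    total = areas.sum()
    if total <= 0:
        raise ValueError("all isotopomer areas are zero within the elution window")
    return areas, areas / total
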