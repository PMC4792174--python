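"""Body-water deuterium enrichment: GC-MS calibration and kinetics.

Body-water enrichment p(t) is measured by acetone hydrogen exchange and
GC-MS: the m/z 59 / m/z 58 ion-intensity ratio is converted to a molar
2H2O fraction through a standard curve, and the resulting time course is
fitted with a first-order rise to plateau,

    p(t) = p_ss * (1 - exp(-k_p * t)),

whose two parameters (plateau p_ss, rate k_p in 1/day) feed the peptide
kinetic model and correct for the delay between the start of labeling and
full equilibration of the body-water pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "StandardCurve",
    "EnrichmentCurve",
    "fit_standard_curve",
    "enrichment_from_ratio",
    "enrichment_at",
    "fit_enrichment_curve",
]

KP_UPPER_BOUND = 50.0  # 1/day; caps the saturated-limit ridge


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration mapping GC-MS intensity ratio → molar 2H2O fraction."""

    slope: float
    intercept: float
    stderr_slope: float
    residual_sd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope == 0:
            raise ValueError("standard-curve slope must be finite and nonzero")


@dataclass(frozen=True)
class EnrichmentCurve:
    """First-order body-water enrichment parameters (p_ss plateau, k_p rate)."""

    p_ss: float
    k_p: float

    def __post_init__(self) -> None:
        # p_ss = 0 is admitted as the degenerate no-label limit; fitted
        # curves always have 0 < p_ss < 1.
        if not 0.0 <= self.p_ss < 1.0:
            raise ValueError(f"p_ss must be in [0, 1), got {self.p_ss}")
        if self.k_p <= 0.0:
            raise ValueError(f"k_p must be positive, got {self.k_p}")

    def p_at(self, t):
        """Enrichment p(t) = p_ss * (1 - exp(-k_p t))."""
        return self.p_ss * (1.0 - np.exp(-self.k_p * np.asarray(t, dtype=float)))


def fit_standard_curve(fractions, ratios) -> StandardCurve:
    """Ordinary least-squares calibration line, fraction regressed on ratio.

    Regressing the known molar fraction on the measured ratio (inverse
    regression) lets the fitted line be applied directly to sample ratios.

    Parameters
    ----------
    fractions
        Known molar 2H2O fractions of the standards (dimensionless).
    ratios
        Measured m/z 59 / m/z 58 intensity ratios.
    """
    fractions = np.asarray(fractions, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    if fractions.shape != ratios.shape:
        raise ValueError("fractions and ratios must have equal length")
    if len(fractions) < 3:
        raise ValueError("need at least 3 standard-curve points")
    if np.ptp(ratios) == 0:
        raise ValueError("degenerate calibration: all measured ratios equal")
    fit = stats.linregress(ratios, fractions)
    resid = fractions - (fit.slope * ratios + fit.intercept)
    dof = max(len(fractions) - 2, 1)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        stderr_slope=float(fit.stderr),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )


def enrichment_from_ratio(curve: StandardCurve, ratio: float) -> float:
    """Convert a measured intensity ratio to a molar enrichment fraction.

    Values outside [0, 1) are clamped with a warning (small negative values
    arise from calibration noise near zero enrichment).
    """
    p = curve.slope * ratio + curve.intercept
    if p < 0.0:
        warnings.warn(f"calibrated enrichment {p:.4g} < 0; clamped to 0")
        return 0.0
    if p >= 1.0:
        warnings.warn(f"calibrated enrichment {p:.4g} >= 1; clamped below 1")
        return np.nextafter(1.0, 0.0)
    return float(p)


def enrichment_at(curve: EnrichmentCurve, t):
    """Evaluate p(t) on the fitted enrichment curve."""
    return curve.p_at(t)


def fit_enrichment_curve(times, enrichments) -> EnrichmentCurve:
    """Least-squares fit of p(t) = p_ss (1 - e^{-k_p t}) to measurements.

    Parameters
    ----------
    times
        Days since the start of labeling (>= 0; at least 3 distinct, one > 0).
    enrichments
        Molar body-water 2H2O fractions at those times.

    Raises
    ------
    ValueError
        On insufficient or degenerate data (e.g. no measurable labeling).
    RuntimeError
        If the optimizer fails to converge.
    """
    t = np.asarray(times, dtype=float)
    p = np.asarray(enrichments, dtype=float)
    if t.shape != p.shape:
        raise ValueError("times and enrichments must have equal length")
    if len(np.unique(t)) < 3 or not np.any(t > 0):
        raise ValueError("need measurements at >= 3 distinct times with some t > 0")
    if np.any(t < 0):
        raise ValueError("negative times")
    labeled = p[t > 0]
    if np.all(np.abs(labeled) < 1e-6):
        raise ValueError("no labeling detected: all enrichments ~ 0 at t > 0")

    p_ss0 = float(np.clip(np.median(labeled), 1e-4, 0.999))
    # crude k_p start: time to half-plateau from the earliest labeled point
    t_min = float(np.min(t[t > 0]))
    kp0 = float(np.clip(np.log(2.0) / t_min, 0.1, KP_UPPER_BOUND / 2))

    def model(tt, p_ss, k_p):
        return p_ss * (1.0 - np.exp(-k_p * tt))

    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            p,
            p0=(p_ss0, kp0),
            bounds=((1e-6, 1e-6), (1.0 - 1e-9, KP_UPPER_BOUND)),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"enrichment-curve fit did not converge: {err}") from err
    return EnrichmentCurve(p_ss=float(popt[0]), k_p=float(popt[1]))
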