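"""Stringency filtering, protein-level roll-up and variability diagnostics.

A fitted peptide series is accepted when it was quantified at >= 4 distinct
time points and either fits well (R^2 >= 0.8) or has a small standard error
of estimate (s.e. <= 0.05).  The two branches are deliberately combined
with OR: slow-turnover peptides produce nearly flat decay curves whose R^2
is necessarily poor even when the data are precise, and the s.e. branch
rescues them.

Protein turnover is reported as the median and (unscaled) median absolute
deviation of the accepted member-peptide rate constants; the experiment-
level quality statistic is the median over multi-peptide proteins of
MAD/median, expressed as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kinetics import KineticFit, half_life

__all__ = [
    "StringencyFilter",
    "ProteinTurnover",
    "apply_filter",
    "protein_rollup",
    "intra_protein_variability",
    "filter_sweep",
]


@dataclass(frozen=True)
class StringencyFilter:
    """Acceptance rule: DP >= min_dp and (R2 >= r2_min or se <= se_max)."""

    min_dp: int = 4
    r2_min: float = 0.8
    se_max: float = 0.05

    def __post_init__(self) -> None:
        if self.min_dp < 2:
            raise ValueError("min_dp must be >= 2")
        # r2_min above 1 is allowed: it disables the R2 branch entirely,
        # which the filter sweep uses to probe empty acceptance.
        if self.se_max <= 0:
            raise ValueError("se_max must be > 0")

    def reason(self, fit: KineticFit) -> str | None:
        """None if the fit is accepted, else a short rejection reason."""
        if fit.dp < self.min_dp:
            return f"DP {fit.dp} < {self.min_dp}"
        if fit.r2 >= self.r2_min or fit.se <= self.se_max:
            return None
        return f"R2 {fit.r2:.3f} < {self.r2_min} and se {fit.se:.3f} > {self.se_max}"


@dataclass(frozen=True)
class ProteinTurnover:
    """Median/MAD turnover summary of one protein within one sample."""

    protein: str
    median_k: float
    mad_k: float
    n_peptides: int
    sample: str = ""

    @property
    def median_half_life(self) -> float:
        return half_life(self.median_k)


def apply_filter(
    fits: Sequence[KineticFit], filt: StringencyFilter | None = None
) -> tuple[list[KineticFit], list[tuple[KineticFit, str]]]:
    """Split fits into accepted and rejected (with reasons), order preserved."""
    if filt is None:
        filt = StringencyFilter()
    accepted: list[KineticFit] = []
    rejected: list[tuple[KineticFit, str]] = []
    for fit in fits:
        why = filt.reason(fit)
        if why is None:
            accepted.append(fit)
        else:
            rejected.append((fit, why))
    return accepted, rejected


def _median_mad(values: np.ndarray) -> tuple[float, float]:
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, mad


def protein_rollup(
    fits: Iterable[KineticFit], sample: str = ""
) -> list[ProteinTurnover]:
    """Aggregate accepted peptide rate constants per protein.

    Returns one record per protein with the median k, the unscaled median
    absolute deviation, and the number of contributing peptides.
    """
    groups: dict[str, list[float]] = {}
    for fit in fits:
        groups.setdefault(fit.protein, []).append(fit.k)
    out = []
    for protein in groups:
        ks = np.asarray(groups[protein], dtype=float)
        med, mad = _median_mad(ks)
        out.append(
            ProteinTurnover(
                protein=protein,
                median_k=med,
                mad_k=mad,
                n_peptides=len(ks),
                sample=sample,
            )
        )
    return out


def intra_protein_variability(rollups: Iterable[ProteinTurnover]) -> float:
    """Experiment-level variability: median over proteins of MAD/median (%).

    Only proteins with >= 2 accepted peptides carry dispersion information
    and enter the statistic.  Values below ~30% indicate internally
    consistent peptide-level rates.
    """
    ratios = [
        r.mad_k / r.median_k
        for r in rollups
        if r.n_peptides >= 2 and r.median_k > 0
    ]
    if not ratios:
        raise ValueError("no protein with >= 2 accepted peptides")
    return float(np.median(ratios)) * 100.0


def filter_sweep(
    fits: Sequence[KineticFit],
    r2_grid: Sequence[float],
    se_grid: Sequence[float],
    min_dp: int = 4,
) -> pd.DataFrame:
    """Evaluate the stringency filter over a grid of (R2, s.e.) cutoffs.

    For each cutoff pair the OR-filter is applied and the accepted-peptide
    count and intra-protein variability are recorded (variability is NaN
    when undefined).  Counts are non-increasing in r2_min at fixed se_max
    and non-decreasing in se_max at fixed r2_min.
    """
    r2_grid = list(r2_grid)
    se_grid = list(se_grid)
    if not r2_grid or not se_grid:
        raise ValueError("cutoff grids must be nonempty")
    rows = []
    for r2_min in r2_grid:
        for se_max in se_grid:
            filt = StringencyFilter(min_dp=min_dp, r2_min=r2_min, se_max=se_max)
            accepted, _ = apply_filter(fits, filt)
            try:
                variability = intra_protein_variability(protein_rollup(accepted))
            except ValueError:
                variability = float("nan")
            rows.append(
                {
                    "r2_min": r2_min,
                    "se_max": se_max,
                    "n_accepted": len(accepted),
                    "variability_pct": variability,
                }
            )
    return pd.DataFrame(rows)
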