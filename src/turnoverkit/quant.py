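"""Label-free protein abundance: XIC intensity and spectral counting (NSAF).

Two complementary measures of relative protein expression within a sample:

* XIC intensity — summed peptide isotope-envelope areas, normalized in
  three stages: (1) to the run's total spectral intensity, (2) to the
  number of quantifiable tryptic peptides the protein can yield (6-30
  residues from full in-silico digestion), and (3) to the within-sample
  total so values sum to one per time point.
* NSAF — length-normalized spectral counts scaled to sum to one:
  NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j).

The tryptic digest cleaves C-terminal to K or R except before proline.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DigestParams",
    "digest",
    "count_quantifiable_peptides",
    "xic_protein_abundance",
    "nsaf",
]


@dataclass(frozen=True)
class DigestParams:
    """Tryptic in-silico digestion settings."""

    missed_cleavages: int = 0
    min_length: int = 6
    max_length: int = 30

    def __post_init__(self) -> None:
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")


_TRYPSIN = re.compile(r"(?<=[KR])(?!P)")


def digest(sequence: str, params: DigestParams | None = None) -> list[str]:
    """Cleave a protein after every K/R not followed by P.

    With zero missed cleavages the returned fragments concatenate back to
    the input.  With ``missed_cleavages = m`` every run of up to m+1
    adjacent fragments is also returned.
    """
    if params is None:
        params = DigestParams()
    if not sequence:
        return []
    fragments = [f for f in _TRYPSIN.split(sequence) if f]
    if params.missed_cleavages == 0:
        return fragments
    out = list(fragments)
    for miss in range(1, params.missed_cleavages + 1):
        for i in range(len(fragments) - miss):
            out.append("".join(fragments[i : i + miss + 1]))
    return out


def count_quantifiable_peptides(sequence: str, params: DigestParams | None = None) -> int:
    """Number of digest products within the quantifiable length range."""
    if params is None:
        params = DigestParams()
    return sum(
        1
        for pep in digest(sequence, params)
        if params.min_length <= len(pep) <= params.max_length
    )


def xic_protein_abundance(
    peptide_areas: pd.DataFrame,
    run_totals: pd.Series,
    peptide_to_protein: dict[str, str],
    protein_sequences: dict[str, str],
    params: DigestParams | None = None,
) -> pd.DataFrame:
    """Three-stage XIC protein abundance, one column per time point.

    Parameters
    ----------
    peptide_areas
        Summed envelope areas, rows indexed by peptide id, one column per
        time point.
    run_totals
        Total spectral intensity of each run (same columns; all > 0).
    peptide_to_protein
        Unique protein assignment of every peptide row.
    protein_sequences
        Protein accession → sequence, for the quantifiable-peptide count.

    Returns
    -------
    DataFrame indexed by protein accession whose columns each sum to 1.
    Proteins with zero quantifiable peptides are excluded with a warning.
    """
    if params is None:
        params = DigestParams()
    run_totals = run_totals.reindex(peptide_areas.columns)
    if run_totals.isna().any() or (run_totals <= 0).any():
        raise ValueError("run totals must be positive for every time point")
    missing = [p for p in peptide_areas.index if p not in peptide_to_protein]
    if missing:
        raise ValueError(f"peptides without protein assignment: {missing[:5]}")

    # stage 1: relative to total spectral intensity of the run
    relative = peptide_areas.div(run_totals, axis=1)

    # stage 2: per-protein sum over peptides, divided by quantifiable count
    proteins = relative.index.map(peptide_to_protein)
    by_protein = relative.groupby(proteins).sum()
    counts = {}
    for accession in by_protein.index:
        n = count_quantifiable_peptides(protein_sequences[accession], params)
        if n == 0:
            warnings.warn(
                f"protein {accession} yields no quantifiable tryptic peptide; excluded"
            )
        else:
            counts[accession] = n
    by_protein = by_protein.loc[list(counts)]
    normalized = by_protein.div(pd.Series(counts), axis=0)

    # stage 3: within-sample closure per time point
    column_sums = normalized.sum(axis=0)
    if (column_sums <= 0).any():
        raise ValueError("zero total abundance in at least one time point")
    return normalized.div(column_sums, axis=1)


def nsaf(spectral_counts, lengths) -> np.ndarray:
    """Normalized spectral abundance factors; returns values summing to 1."""
    counts = np.asarray(spectral_counts, dtype=float)
    lens = np.asarray(lengths, dtype=float)
    if counts.shape != lens.shape:
        raise ValueError("spectral_counts and lengths must have equal length")
    if np.any(lens <= 0):
        raise ValueError("protein lengths must be positive")
    saf = counts / lens
    total = saf.sum()
    if total == 0:
        raise ValueError("all spectral counts are zero")
    return saf / total
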