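"""Dataset-level glue: annotate peptides, fit every series, build hl.out.

Ties the per-peptide primitives together for whole-table processing: given
an (ID, t, A_0) series table and a peptide metadata table, compute each
peptide's model constants (a from the isotope envelope, N from the
labeling-site table), fit the turnover rate, and assemble the 14-column
fit table.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from .bodywater import EnrichmentCurve
from .chem import (
    isotope_envelope,
    load_abundance_table,
    load_modification_table,
    load_residue_table,
    natural_a0,
    peptide_composition,
)
from .kinetics import KineticFit, KineticModelParams, PeptideTimeSeries, fit_k
from .sites import count_sites, load_site_table

__all__ = ["annotate_peptides", "fit_dataset", "fits_to_hl_out"]

log = logging.getLogger("turnoverkit")


def annotate_peptides(peptides: pd.DataFrame) -> pd.DataFrame:
    """Add the model constants a and N to a peptide metadata table.

    Expects columns ID, UniProt, Peptide, z and optionally ``mods``
    (semicolon-separated names); existing a/N columns are kept.
    """
    out = peptides.copy()
    residue_table = load_residue_table()
    abundance_table = load_abundance_table()
    mod_table = load_modification_table()
    site_table = load_site_table()
    if "a" not in out.columns:
        a_values = []
        for _, row in out.iterrows():
            mods = _parse_mods(row.get("mods", ""))
            comp = peptide_composition(
                row["Peptide"], mods, residue_table=residue_table, mod_table=mod_table
            )
            a_values.append(natural_a0(isotope_envelope(comp, abundance_table, n_peaks=1)))
        out["a"] = a_values
    if "N" not in out.columns:
        out["N"] = [count_sites(p, site_table) for p in out["Peptide"]]
    return out


def _parse_mods(cell) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return ()
    return tuple(m.strip() for m in str(cell).split(";") if m.strip())


def fit_dataset(
    series: pd.DataFrame,
    peptides: pd.DataFrame,
    enrichment: EnrichmentCurve,
    optimizer: str = "nelder-mead",
    min_dp: int = 4,
) -> list[KineticFit]:
    """Fit the turnover rate of every peptide time series in a dataset.

    Peptides with fewer than ``min_dp`` distinct time points are skipped
    with a warning (they cannot pass the stringency filter and the fit
    would be under-determined).
    """
    peptides = annotate_peptides(peptides)
    by_id = dict(tuple(series.groupby("ID", sort=False)))
    fits: list[KineticFit] = []
    n_skipped = 0
    for _, row in peptides.iterrows():
        pid = row["ID"]
        if pid not in by_id:
            log.warning("peptide %s has no time-series data; skipped", pid)
            continue
        obs = by_id[pid]
        ts = PeptideTimeSeries(
            peptide_id=pid,
            t=obs["t"].to_numpy(),
            a0=obs["A_0"].to_numpy(),
            protein=row.get("UniProt", ""),
            sequence=row.get("Peptide", ""),
            charge=int(row.get("z", 0)),
        )
        if ts.dp < min_dp:
            n_skipped += 1
            log.warning("peptide %s quantified at %d < %d time points; skipped", pid, ts.dp, min_dp)
            continue
        params = KineticModelParams(
            a=float(row["a"]), n_sites=float(row["N"]), enrichment=enrichment
        )
        fits.append(fit_k(ts, params, optimizer=optimizer))
    log.info("fitted %d peptide series (%d skipped below %d time points)", len(fits), n_skipped, min_dp)
    return fits


def fits_to_hl_out(
    fits: Sequence[KineticFit],
    peptides: pd.DataFrame,
    enrichment: EnrichmentCurve,
) -> pd.DataFrame:
    """Assemble the 14-column fit table from fits and peptide metadata."""
    peptides = annotate_peptides(peptides).set_index("ID")
    rows = []
    for fit in fits:
        meta = peptides.loc[fit.peptide_id]
        rows.append(
            {
                "ID": fit.peptide_id,
                "UniProt": meta.get("UniProt", ""),
                "Peptide": meta.get("Peptide", ""),
                "DP": fit.dp,
                "z": int(meta.get("z", 0)),
                "mi": int(meta.get("mi", 0)),
                "SS": fit.ss,
                "a": float(meta["a"]),
                "pss": enrichment.p_ss,
                "kp": enrichment.k_p,
                "N": float(meta["N"]),
                "k": fit.k,
                "dk": fit.dk,
                "R2": fit.r2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ID", "UniProt", "Peptide", "DP", "z", "mi", "SS",
            "a", "pss", "kp", "N", "k", "dk", "R2",
        ],
    )
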