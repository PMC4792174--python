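"""Deuterium-accessible labeling sites per peptide.

During heavy-water labeling only a subset of a peptide's hydrogens can
acquire deuterium from body water via intermediary metabolism.  The
effective number of such sites, N, is estimated by summing per-residue
literature values measured in vivo (Commerford-lineage exchange data);
N enters the kinetic model through the plateau A0,max = a*(1-p)^N.

Modifications do not alter N here: no modification-specific site counts
are available, and the contribution of a modification's hydrogens is small
relative to the backbone and side-chain sites.
"""

from __future__ import annotations

from typing import Mapping

from .chem import _read_tsv

__all__ = ["load_site_table", "count_sites"]


def load_site_table(path=None) -> dict[str, float]:
    """Residue one-letter code → effective accessible labeling sites."""
    if path is None:
        rows = _read_tsv("labeling_sites.tsv")
    else:
        rows = [
            l.split("\t") for l in open(path) if l.strip() and not l.startswith("#")
        ]
    table = {r[0]: float(r[1]) for r in rows}
    for res, val in table.items():
        if val < 0:
            raise ValueError(f"negative site count for residue {res!r}")
    return table


def count_sites(sequence: str, table: Mapping[str, float] | None = None) -> float:
    """Sum per-residue accessible-site values over a peptide sequence.

    Additive over concatenation: ``count_sites(s1 + s2)`` equals
    ``count_sites(s1) + count_sites(s2)``.

    Raises
    ------
    ValueError
        If a residue in the sequence has no table entry.
    """
    if table is None:
        table = load_site_table()
    total = 0.0
    for res in sequence:
        if res not in table:
            raise ValueError(f"residue {res!r} missing from labeling-site table")
        total += table[res]
    return total
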