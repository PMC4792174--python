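"""Peptide elemental composition and natural-abundance isotope envelopes.

In heavy-water labeling experiments the observable of interest is the
fractional abundance of the monoisotopic (0th) mass isotopomer, ``A0``.
Before any label is present, ``A0`` equals *a*, the 0th-isotopomer fraction
dictated purely by the peptide's elemental composition and the natural
abundance of heavy isotopes.  This module computes that quantity: it sums
residue formulas (plus one terminal water and any modification deltas) and
convolves per-element isotope distributions into the peptide's envelope.

Mass isotopomers are indexed by integer nominal-mass offset from the
monoisotopic peak; fine structure within one nominal offset is aggregated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ElementalComposition",
    "IsotopeAbundanceTable",
    "load_residue_table",
    "load_abundance_table",
    "load_modification_table",
    "peptide_composition",
    "isotope_envelope",
    "natural_a0",
]

_CANONICAL_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ElementalComposition:
    """Atom counts per element for one molecular species."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {e: int(n) for e, n in self.counts.items() if n != 0}
        for element, n in clean.items():
            if n < 0:
                raise ValueError(f"negative atom count for element {element!r}: {n}")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return ElementalComposition(merged)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def __str__(self) -> str:
        return "".join(f"{e}{n}" for e, n in sorted(self.counts.items()))


@dataclass(frozen=True)
class IsotopeAbundanceTable:
    """Per-element isotope distributions over integer mass offsets.

    ``table[element]`` is a sequence of ``(mass_offset, abundance)`` pairs;
    abundances for each element must sum to 1 within 1e-9.
    """

    table: Mapping[str, Sequence[tuple[int, float]]]

    def __post_init__(self) -> None:
        for element, pairs in self.table.items():
            total = sum(a for _, a in pairs)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"isotope abundances for {element!r} sum to {total}, not 1"
                )
            for offset, a in pairs:
                if not 0.0 <= a <= 1.0:
                    raise ValueError(f"abundance out of [0,1] for {element!r}: {a}")
                if offset < 0:
                    raise ValueError(f"negative mass offset for {element!r}")

    def distribution(self, element: str) -> np.ndarray:
        """Dense abundance vector indexed by mass offset for one element."""
        if element not in self.table:
            raise KeyError(f"element {element!r} missing from isotope table")
        pairs = self.table[element]
        dist = np.zeros(max(o for o, _ in pairs) + 1)
        for offset, a in pairs:
            dist[offset] += a
        return dist

    def lightest(self, element: str) -> float:
        """Abundance of the monoisotopic (offset-0) species."""
        return float(self.distribution(element)[0])


def _read_tsv(name: str) -> list[list[str]]:
    text = resources.files("turnoverkit.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def load_residue_table(path=None) -> dict[str, ElementalComposition]:
    """Residue → elemental composition (peptide-bond form, no water)."""
    if path is None:
        rows = _read_tsv("residue_formulas.tsv")
    else:
        rows = [l.split("\t") for l in open(path) if l.strip() and not l.startswith("#")]
    elements = ("C", "H", "N", "O", "S")
    return {
        r[0]: ElementalComposition(dict(zip(elements, map(int, r[1:6]))))
        for r in rows
    }


def load_abundance_table(path=None) -> IsotopeAbundanceTable:
    if path is None:
        rows = _read_tsv("isotope_abundances.tsv")
    else:
        rows = [l.split("\t") for l in open(path) if l.strip() and not l.startswith("#")]
    table: dict[str, list[tuple[int, float]]] = {}
    for element, offset, abundance in rows:
        table.setdefault(element, []).append((int(offset), float(abundance)))
    return IsotopeAbundanceTable(table)


def load_modification_table(path=None) -> dict[str, dict[str, int]]:
    """Modification name → elemental-composition delta (may be negative)."""
    if path is None:
        rows = _read_tsv("modifications.tsv")
    else:
        rows = [l.split("\t") for l in open(path) if l.strip() and not l.startswith("#")]
    elements = ("C", "H", "N", "O", "S", "P")
    return {r[0]: dict(zip(elements, map(int, r[1:7]))) for r in rows}


_WATER = ElementalComposition({"H": 2, "O": 1})


def peptide_composition(
    sequence: str,
    mods: Iterable[str] = (),
    residue_table: Mapping[str, ElementalComposition] | None = None,
    mod_table: Mapping[str, Mapping[str, int]] | None = None,
) -> ElementalComposition:
    """Elemental composition of a peptide: residues + one water + mod deltas.

    Parameters
    ----------
    sequence
        Peptide in one-letter code (the 20 canonical residues).
    mods
        Names of applied modifications; each must exist in ``mod_table``.
        A name may repeat to apply the same modification more than once.

    Raises
    ------
    ValueError
        On an unknown residue letter (reporting its position) or an
        unknown modification name, or if a delta would drive an element
        count negative.
    """
    if residue_table is None:
        residue_table = load_residue_table()
    if mod_table is None:
        mod_table = load_modification_table()
    if not sequence:
        raise ValueError("empty peptide sequence")

    counts: Counter[str] = Counter(_WATER.counts)
    for i, res in enumerate(sequence):
        if res not in _CANONICAL_RESIDUES or res not in residue_table:
            raise ValueError(f"unknown residue {res!r} at position {i} in {sequence!r}")
        counts.update(residue_table[res].counts)

    for name in mods:
        if name not in mod_table:
            raise ValueError(f"unknown modification {name!r}")
        for element, delta in mod_table[name].items():
            counts[element] += delta
            if counts[element] < 0:
                raise ValueError(
                    f"modification {name!r} drives {element} count negative"
                )
    return ElementalComposition(counts)


def isotope_envelope(
    comp: ElementalComposition,
    table: IsotopeAbundanceTable | None = None,
    n_peaks: int | None = 5,
) -> np.ndarray:
    """Natural-abundance mass-isotopomer envelope of a composition.

    The envelope is the discrete convolution, by integer mass offset, of the
    isotope distribution of every atom.  Per element the n-atom distribution
    is computed by binary exponentiation of the single-atom polynomial; the
    per-element results are then convolved together.

    Parameters
    ----------
    n_peaks
        Truncate to this many isotopomers (offsets ``0 .. n_peaks-1``).
        ``None`` keeps the full untruncated envelope, which sums to 1.
    """
    if table is None:
        table = load_abundance_table()
    if n_peaks is not None and n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")

    envelope = np.array([1.0])
    for element, count in comp.counts.items():
        single = table.distribution(element)  # raises KeyError if absent
        envelope = np.convolve(envelope, _poly_power(single, count))
    if n_peaks is not None:
        envelope = envelope[:n_peaks]
    return envelope


def _poly_power(dist: np.ndarray, n: int) -> np.ndarray:
    """dist convolved with itself n times (binary exponentiation)."""
    result = np.array([1.0])
    base = dist
    while n > 0:
        if n & 1:
            result = np.convolve(result, base)
        n >>= 1
        if n:
            base = np.convolve(base, base)
    return result


def natural_a0(envelope: np.ndarray) -> float:
    """The unlabeled 0th-isotopomer fraction *a* — the envelope's first entry."""
    if len(envelope) == 0:
        raise ValueError("empty envelope")
    return float(envelope[0])
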