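"""Elemental compositions, monoisotopic masses and natural isotope envelopes.

The quantification strategy in this package compares an endogenous (light,
CH3-CO) acetyl peak with a chemically installed (heavy, CD3-CO) acetyl peak
3.0188 Da higher per labeled lysine. At the resolution of DIA fragment
quantification the +3k natural isotopologue of the light species (mostly
three 13C atoms) is not resolved from the heavy monoisotopic peak, so the
heavy signal must be corrected by the light envelope ratio a_{3k}/a_0.

Everything here works on nominal (integer Da) isotopologue offsets, which is
exactly the coincidence the correction targets. A fixed isotope table
(IUPAC-2013-style values) is shipped so results do not depend on the runtime
environment. Deuterium at label positions is modeled as a separate "element"
``D`` that is isotopically pure.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ISOTOPES",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "WATER",
    "ElementalComposition",
    "IsotopeEnvelope",
    "mass_of",
    "isotope_envelope",
]

#: (mass in Da, natural abundance) per isotope, monoisotopic (most abundant)
#: isotope first. Offsets from the monoisotopic mass are nominal (integer Da).
ISOTOPES: dict[str, tuple[tuple[float, float], ...]] = {
    "H": ((1.0078250319, 0.999885), (2.0141017781, 0.000115)),
    "C": ((12.0, 0.9893), (13.0033548378, 0.0107)),
    "N": ((14.0030740052, 0.99636), (15.0001088984, 0.00364)),
    "O": ((15.9949146221, 0.99757), (16.9991315, 0.00038), (17.9991604, 0.00205)),
    "S": (
        (31.97207069, 0.9499),
        (32.97145850, 0.0075),
        (33.96786683, 0.0425),
        (35.96708088, 0.0001),
    ),
    # Deuterium as installed by the heavy acetyl label: treated as pure 2H.
    "D": ((2.0141017781, 1.0),),
}

MONOISOTOPIC_MASS: dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}

PROTON_MASS = 1.00727646


class ElementalComposition:
    """An element -> count map (C, H, N, O, S and label deuterium D).

    Addition is element-wise; counts in a *delta* (e.g. the heavy-acetyl
    modification, C2 H-1 D3 O) may be negative, but a composition handed to
    :func:`isotope_envelope` must be non-negative throughout.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargts: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kwargts:
            for el, n in source.items():
                if el not in ISOTOPES:
                    raise ValueError(f"unknown element symbol: {el!r}")
                merged[el] = merged.get(el, 0) + int(n)
        self._counts = {el: n for el, n in merged.items() if n != 0}

    @property
    def counts(self) -> dict[str, int]:
        return dict(self._counts)

    def items(self):
        return self._counts.items()

    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self._counts)
        for el, n in other.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalComposition(merged)

    def __mul__(self, k: int) -> "ElementalComposition":
        return ElementalComposition({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other) -> bool:
        return isinstance(other, ElementalComposition) and self._counts == other._counts

    def __hash__(self) -> int:
        return hash(self.key())

    def key(self) -> tuple[tuple[str, int], ...]:
        """Canonical hashable form (sorted element/count pairs)."""
        return tuple(sorted(self._counts.items()))

    def is_valid(self) -> bool:
        """True when all counts are non-negative (a physical composition)."""
        return all(n >= 0 for n in self._counts.values())

    @property
    def mass(self) -> float:
        return mass_of(self)

    def __repr__(self) -> str:
        body = "".join(f"{el}{n}" for el, n in self.key())
        return f"ElementalComposition({body or 'empty'})"


def mass_of(composition: ElementalComposition) -> float:
    """Monoisotopic mass (Da) of a composition from the shipped table.

    The empty composition has mass 0. Deterministic: a plain weighted sum of
    per-element monoisotopic masses.
    """
    return float(sum(MONOISOTOPIC_MASS[el] * n for el, n in composition.items()))


WATER = ElementalComposition({"H": 2, "O": 1})


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Relative abundances indexed by nominal isotopologue offset (Da).

    Index 0 is the monoisotopic peak. Values are fractions of the untruncated
    total (which is 1), so a truncated envelope sums to slightly less than 1;
    nothing is renormalized after truncation.
    """

    abundances: tuple[float, ...]

    def abundance(self, offset: int) -> float:
        """Abundance at a nominal offset; 0.0 beyond the stored range."""
        if 0 <= offset < len(self.abundances):
            return self.abundances[offset]
        return 0.0

    def correction_ratio(self, k: int) -> float:
        """a_{3k}/a_0 -- the light-into-heavy leakage ratio for k labels."""
        if k < 1:
            raise ValueError("correction ratio is defined for k >= 1 labels")
        return self.abundance(3 * k) / self.abundances[0]

    def __len__(self) -> int:
        return len(self.abundances)


def _element_offset_dist(element: str) -> np.ndarray:
    """Single-atom abundance vector indexed by nominal mass offset."""
    isotopes = ISOTOPES[element]
    mono = isotopes[0][0]
    max_off = int(round(isotopes[-1][0] - mono))
    dist = np.zeros(max_off + 1)
    for mass, abundance in isotopes:
        dist[int(round(mass - mono))] += abundance
    return dist


def _convolve_trunc(a: np.ndarray, b: np.ndarray, length: int) -> np.ndarray:
    return np.convolve(a, b)[:length]


def _element_power(element: str, n: int, length: int) -> np.ndarray:
    """Offset distribution of n atoms of one element, truncated to `length`.

    Exponentiation by squaring; truncation mid-way is exact for the retained
    offsets because offsets only ever add.
    """
    base = _element_offset_dist(element)[:length]
    result = np.array([1.0])
    while n:
        if n & 1:
            result = _convolve_trunc(result, base, length)
        n >>= 1
        if n:
            base = _convolve_trunc(base, base, length)
    return result


@lru_cache(maxsize=65536)
def _envelope_cached(comp_key: tuple[tuple[str, int], ...], max_iso: int) -> tuple[float, ...]:
    length = max_iso + 1
    dist = np.array([1.0])
    for el, n in comp_key:
        dist = _convolve_trunc(dist, _element_power(el, n, length), length)
    # Stop early once the cumulative abundance is within 1e-9 of the
    # untruncated total, whichever comes first (documented truncation rule).
    cum = np.cumsum(dist)
    cut = int(np.searchsorted(cum, 1.0 - 1e-9)) + 1
    return tuple(dist[: min(cut, length)])


def isotope_envelope(composition: ElementalComposition, max_iso: int = 10) -> IsotopeEnvelope:
    """Natural isotope envelope of a composition by nominal mass offset.

    Computed by convolving per-element isotopologue distributions (each
    aggregated by nominal offset) across all atoms. Deuterium positions are
    isotopically pure and contribute nothing beyond offset 0.

    Parameters
    ----------
    composition:
        Non-negative elemental composition.
    max_iso:
        Largest offset retained. The envelope may be shorter if the
        cumulative abundance reaches 1 - 1e-9 earlier. Values are fractions
        of the untruncated total (no renormalization).
    """
    if not composition.is_valid():
        raise ValueError(f"composition has negative counts: {composition!r}")
    if max_iso < 0:
        raise ValueError("max_iso must be >= 0")
    return IsotopeEnvelope(_envelope_cached(composition.key(), max_iso))
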