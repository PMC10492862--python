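"""Peptidoforms, in-silico protease digestion and heavy/light fragment pairs.

The chemical-labeling workflow modeled here acetylates every unmodified
lysine with D6-acetic anhydride before digestion, so lysines never present a
tryptic cleavage site: trypsin effectively cuts after arginine only, and GluC
cuts after glutamate (optionally also aspartate). Each lysine in a peptide
then carries exactly one acetyl group, either endogenous (light, +42.0106 Da)
or chemical (heavy, +45.0294 Da).

For every b/y fragment that covers at least one acetyl-lysine we emit a
light/heavy pair: the two m/z values differ by 3k x 1.0062767 / z (k =
covered acetyls) and the pair carries the envelope-correction ratio
a_{3k}/a_0 of the light fragment, used downstream to strip natural-isotope
leakage of the light species out of the heavy channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem import (
    PROTON_MASS,
    WATER,
    ElementalComposition,
    isotope_envelope,
    mass_of,
)

__all__ = [
    "RESIDUE_COMPOSITIONS",
    "MODIFICATIONS",
    "ACETYL_LIGHT",
    "ACETYL_HEAVY",
    "Peptidoform",
    "FragmentPair",
    "digest",
    "composition_of_peptidoform",
    "fragment_composition",
    "fragment_mz",
    "build_pair_table",
    "pairs_to_frame",
    "peptidoform_id",
    "parse_peptidoform_id",
    "PAIR_TABLE_COLUMNS",
]

# Residue (= amino acid minus water) compositions for the 20 canonical
# residues.
RESIDUE_COMPOSITIONS: dict[str, ElementalComposition] = {
    "G": ElementalComposition(C=2, H=3, N=1, O=1),
    "A": ElementalComposition(C=3, H=5, N=1, O=1),
    "S": ElementalComposition(C=3, H=5, N=1, O=2),
    "P": ElementalComposition(C=5, H=7, N=1, O=1),
    "V": ElementalComposition(C=5, H=9, N=1, O=1),
    "T": ElementalComposition(C=4, H=7, N=1, O=2),
    "C": ElementalComposition(C=3, H=5, N=1, O=1, S=1),
    "L": ElementalComposition(C=6, H=11, N=1, O=1),
    "I": ElementalComposition(C=6, H=11, N=1, O=1),
    "N": ElementalComposition(C=4, H=6, N=2, O=2),
    "D": ElementalComposition(C=4, H=5, N=1, O=3),
    "Q": ElementalComposition(C=5, H=8, N=2, O=2),
    "K": ElementalComposition(C=6, H=12, N=2, O=1),
    "E": ElementalComposition(C=5, H=7, N=1, O=3),
    "M": ElementalComposition(C=5, H=9, N=1, O=1, S=1),
    "H": ElementalComposition(C=6, H=7, N=3, O=1),
    "F": ElementalComposition(C=9, H=9, N=1, O=1),
    "R": ElementalComposition(C=6, H=12, N=4, O=1),
    "Y": ElementalComposition(C=9, H=9, N=1, O=2),
    "W": ElementalComposition(C=11, H=10, N=2, O=1),
}

ACETYL_LIGHT = "acetyl-light"
ACETYL_HEAVY = "acetyl-heavy"

#: Modification composition deltas. The heavy acetyl replaces the CH3 of the
#: light acetyl with CD3: net C2 H-1 D3 O, i.e. +3.0188302 Da over light.
MODIFICATIONS: dict[str, ElementalComposition] = {
    ACETYL_LIGHT: ElementalComposition(C=2, H=2, O=1),
    ACETYL_HEAVY: ElementalComposition(C=2, H=-1, D=3, O=1),
    "carbamidomethyl": ElementalComposition(C=2, H=3, N=1, O=1),
    "oxidation": ElementalComposition(O=1),
}

_ACETYL_FORMS = frozenset({ACETYL_LIGHT, ACETYL_HEAVY})

_MOD_CODES = {
    ACETYL_LIGHT: "ac",
    ACETYL_HEAVY: "hac",
    "carbamidomethyl": "cam",
    "oxidation": "ox",
}
_CODE_MODS = {v: k for k, v in _MOD_CODES.items()}


@dataclass(frozen=True)
class Peptidoform:
    """A peptide with a specific modification set, located in its protein.

    Coordinates are 1-based inclusive: ``start``/``end`` in the protein,
    modification positions within the peptide. Every lysine must carry
    exactly one acetyl form -- the labeling chemistry leaves no free lysine
    (up to the labeling efficiency, which is handled as signal, not as a
    modification state).
    """

    protein_id: str
    start: int
    end: int
    sequence: str
    modifications: tuple[tuple[int, str], ...] = ()
    charge: int = 2

    def __post_init__(self):
        object.__setattr__(self, "modifications", tuple(self.modifications))
        n = len(self.sequence)
        if n == 0:
            raise ValueError("empty peptide sequence")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in RESIDUE_COMPOSITIONS:
                raise ValueError(f"unknown residue {aa!r} at peptide position {i}")
        if self.end - self.start + 1 != n:
            raise ValueError("end - start + 1 must equal the peptide length")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")
        acetyl_positions: list[int] = []
        for pos, name in self.modifications:
            if not 1 <= pos <= n:
                raise ValueError(f"modification position {pos} outside [1, {n}]")
            if name not in MODIFICATIONS:
                raise ValueError(f"unknown modification {name!r}")
            if name in _ACETYL_FORMS:
                if self.sequence[pos - 1] != "K":
                    raise ValueError(f"acetyl at position {pos} is not on a lysine")
                acetyl_positions.append(pos)
        lysines = [i for i, aa in enumerate(self.sequence, start=1) if aa == "K"]
        if sorted(acetyl_positions) != lysines:
            raise ValueError(
                "every K must carry exactly one of acetyl-light/acetyl-heavy"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def acetyl_sites(self) -> list[tuple[int, str]]:
        """(peptide position, form) of each acetylated lysine."""
        return [(p, m) for p, m in self.modifications if m in _ACETYL_FORMS]

    def with_all_acetyl(self, form: str) -> "Peptidoform":
        """Copy with every lysine's acetyl switched to `form`."""
        if form not in _ACETYL_FORMS:
            raise ValueError(f"not an acetyl form: {form!r}")
        mods = tuple(
            (p, form if m in _ACETYL_FORMS else m) for p, m in self.modifications
        )
        return Peptidoform(
            self.protein_id, self.start, self.end, self.sequence, mods, self.charge
        )


def composition_of_peptidoform(p: Peptidoform) -> ElementalComposition:
    """Neutral elemental composition: residues + water + modification deltas."""
    comp = WATER
    for aa in p.sequence:
        comp = comp + RESIDUE_COMPOSITIONS[aa]
    for _, name in p.modifications:
        comp = comp + MODIFICATIONS[name]
    return comp


def digest(
    protein: str,
    max_missed: int = 1,
    length_bounds: tuple[int, int] | None = (6, 30),
    gluc_cuts: str = "E",
    block_proline: bool = True,
) -> list[tuple[int, int]]:
    """Trypsin+GluC digestion spans with acetyl-blocked lysines.

    Cleavage occurs C-terminal to R (trypsin; K is chemically acetylated and
    never cleaved) and C-terminal to E (GluC; set ``gluc_cuts="ED"`` for the
    buffer-dependent E+D specificity), suppressed before proline by default.
    Returns all 1-based inclusive spans with at most ``max_missed`` internal
    cleavage sites and, if ``length_bounds`` is given, length within bounds.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    if gluc_cuts not in ("E", "ED"):
        raise ValueError("gluc_cuts must be 'E' or 'ED'")
    cut_after = set("R") | set(gluc_cuts)
    n = len(protein)
    boundaries = [0]
    for i in range(1, n):  # potential cut between residues i and i+1 (1-based)
        if protein[i - 1] in cut_after and not (block_proline and protein[i] == "P"):
            boundaries.append(i)
    boundaries.append(n)

    spans: list[tuple[int, int]] = []
    n_seg = len(boundaries) - 1
    for a in range(n_seg):
        for b in range(a, min(a + max_missed + 1, n_seg)):
            start, end = boundaries[a] + 1, boundaries[b + 1]
            length = end - start + 1
            if length_bounds is None or length_bounds[0] <= length <= length_bounds[1]:
                spans.append((start, end))
    return spans


def fragment_composition(p: Peptidoform, kind: str, index: int) -> ElementalComposition:
    """Neutral composition of a b or y fragment.

    b_i sums the first ``index`` residues (plus their modifications); y_i
    sums the last ``index`` residues plus water, so that
    neutral(b_i) + neutral(y_{n-i}) equals the neutral peptide composition.
    """
    n = p.length
    if kind not in ("b", "y"):
        raise ValueError("fragment kind must be 'b' or 'y'")
    # index == n (the full-length ion) is tolerated for mass bookkeeping;
    # pair generation only enumerates the informative range 1..n-1.
    if not 1 <= index <= n:
        raise ValueError(f"fragment index {index} outside [1, {n}]")
    if kind == "b":
        residues = range(1, index + 1)
        comp = ElementalComposition()
    else:
        residues = range(n - index + 1, n + 1)
        comp = WATER
    covered = set(residues)
    for i in residues:
        comp = comp + RESIDUE_COMPOSITIONS[p.sequence[i - 1]]
    for pos, name in p.modifications:
        if pos in covered:
            comp = comp + MODIFICATIONS[name]
    return comp


def fragment_mz(p: Peptidoform, kind: str, index: int) -> float:
    """m/z (Th) of a b/y fragment at the peptidoform's charge."""
    neutral = mass_of(fragment_composition(p, kind, index))
    return (neutral + p.charge * PROTON_MASS) / p.charge


@dataclass(frozen=True)
class FragmentPair:
    """A light/heavy acetyl fragment-ion pair generated in silico."""

    peptidoform: Peptidoform  # light-state peptidoform
    fragment_kind: str
    fragment_index: int
    charge: int
    n_acetyl_sites_covered: int
    light_mz: float
    heavy_mz: float
    correction_ratio: float
    #: protein coordinate of the covered lysine when exactly one is covered
    site_position: int | None = None


def _covered_positions(p: Peptidoform, kind: str, index: int) -> range:
    if kind == "b":
        return range(1, index + 1)
    return range(p.length - index + 1, p.length + 1)


def fragment_pairs(
    p: Peptidoform, charges: Sequence[int] = (1, 2)
) -> list[FragmentPair]:
    """All b/y light/heavy pairs of one peptidoform covering >= 1 acetyl-K.

    The peptidoform is interpreted in its all-light state; the heavy partner
    is generated by switching every acetyl to the heavy form. Fragments
    covering no lysine have no pair and are skipped.
    """
    light = p.with_all_acetyl(ACETYL_LIGHT)
    heavy = p.with_all_acetyl(ACETYL_HEAVY)
    acetyl_pos = [pos for pos, _ in light.acetyl_sites()]
    out: list[FragmentPair] = []
    for kind in ("b", "y"):
        for index in range(1, p.length - 1 + 1):
            covered = _covered_positions(p, kind, index)
            k = sum(1 for pos in acetyl_pos if pos in covered)
            if k == 0:
                continue
            light_comp = fragment_composition(light, kind, index)
            heavy_comp = fragment_composition(heavy, kind, index)
            env = isotope_envelope(light_comp, max_iso=max(10, 3 * k + 2))
            ratio = env.correction_ratio(k)
            site = None
            if k == 1:
                pep_pos = next(pos for pos in acetyl_pos if pos in covered)
                site = light.start + pep_pos - 1
            light_neutral = mass_of(light_comp)
            heavy_neutral = mass_of(heavy_comp)
            for z in charges:
                out.append(
                    FragmentPair(
                        peptidoform=light,
                        fragment_kind=kind,
                        fragment_index=index,
                        charge=z,
                        n_acetyl_sites_covered=k,
                        light_mz=(light_neutral + z * PROTON_MASS) / z,
                        heavy_mz=(heavy_neutral + z * PROTON_MASS) / z,
                        correction_ratio=ratio,
                        site_position=site,
                    )
                )
    return out


def build_pair_table(
    peptidoforms: Iterable[Peptidoform], charges: Sequence[int] = (1, 2)
) -> list[FragmentPair]:
    """Fragment pairs for a collection of peptidoforms (all-light input)."""
    pairs: list[FragmentPair] = []
    for p in peptidoforms:
        pairs.extend(fragment_pairs(p, charges))
    return pairs


PAIR_TABLE_COLUMNS = [
    "protein_id",
    "peptide_start",
    "peptide_end",
    "peptidoform_id",
    "charge",
    "fragment_kind",
    "fragment_index",
    "k_acetyl",
    "site_position",
    "light_mz",
    "heavy_mz",
    "correction_ratio",
]


def pairs_to_frame(pairs: Sequence[FragmentPair]) -> pd.DataFrame:
    """Tabulate fragment pairs with one row per (fragment, charge)."""
    rows = [
        (
            fp.peptidoform.protein_id,
            fp.peptidoform.start,
            fp.peptidoform.end,
            peptidoform_id(fp.peptidoform),
            fp.charge,
            fp.fragment_kind,
            fp.fragment_index,
            fp.n_acetyl_sites_covered,
            fp.site_position,
            fp.light_mz,
            fp.heavy_mz,
            fp.correction_ratio,
        )
        for fp in pairs
    ]
    return pd.DataFrame(rows, columns=PAIR_TABLE_COLUMNS)


def peptidoform_id(p: Peptidoform) -> str:
    """Stable text id: ``PROT:start-end:ac@2;cam@5`` (charge kept separate)."""
    mods = ";".join(
        f"{_MOD_CODES[name]}@{pos}"
        for pos, name in sorted(p.modifications)
    )
    return f"{p.protein_id}:{p.start}-{p.end}:{mods}"


def parse_peptidoform_id(
    pid: str, sequences: Mapping[str, str], charge: int = 2
) -> Peptidoform:
    """Rebuild a peptidoform from its id and the protein FASTA sequences."""
    try:
        protein_id, span, modstring = pid.rsplit(":", 2)
        start_s, end_s = span.split("-")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(f"malformed peptidoform id: {pid!r}") from exc
    if protein_id not in sequences:
        raise ValueError(f"unknown protein {protein_id!r} in peptidoform id")
    seq = sequences[protein_id][start - 1 : end]
    if len(seq) != end - start + 1:
        raise ValueError(f"span {start}-{end} outside protein {protein_id!r}")
    mods: list[tuple[int, str]] = []
    if modstring:
        for token in modstring.split(";"):
            code, pos_s = token.split("@")
            if code not in _CODE_MODS:
                raise ValueError(f"unknown modification code {code!r} in {pid!r}")
            mods.append((int(pos_s), _CODE_MODS[code]))
    return Peptidoform(protein_id, start, end, seq, tuple(mods), charge)
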