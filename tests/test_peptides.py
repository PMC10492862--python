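"""Digestion, peptidoforms, fragment masses and heavy/light pair generation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acetylstoich.chem import PROTON_MASS, mass_of
from acetylstoich.peptides import (
    ACETYL_HEAVY,
    ACETYL_LIGHT,
    Peptidoform,
    build_pair_table,
    composition_of_peptidoform,
    digest,
    fragment_composition,
    fragment_mz,
    fragment_pairs,
    pairs_to_frame,
    parse_peptidoform_id,
    peptidoform_id,
)

LABEL_GAP = 3 * 1.0062767462  # 3 x (2H - 1H)


def make_peptidoform(sequence, heavy=False, charge=1, protein="P1", start=1):
    form = ACETYL_HEAVY if heavy else ACETYL_LIGHT
    mods = tuple(
        (i, form) for i, aa in enumerate(sequence, start=1) if aa == "K"
    )
    return Peptidoform(
        protein, start, start + len(sequence) - 1, sequence, mods, charge
    )


class TestCompositions:
    def test_peptide_golden_mass(self):
        p = make_peptidoform("PEPTIDE")
        assert mass_of(composition_of_peptidoform(p)) == pytest.approx(
            799.3600, abs=1e-3
        )

    def test_glycine_formula(self):
        comp = composition_of_peptidoform(make_peptidoform("G"))
        assert comp.counts == {"C": 2, "H": 5, "N": 1, "O": 2}

    def test_heavy_light_mass_gap(self):
        light = make_peptidoform("AK")
        heavy = make_peptidoform("AK", heavy=True)
        gap = mass_of(composition_of_peptidoform(heavy)) - mass_of(
            composition_of_peptidoform(light)
        )
        assert gap == pytest.approx(3.018830, abs=1e-6)

    def test_unknown_residue_reports_position(self):
        with pytest.raises(ValueError, match="position 3"):
            Peptidoform("P1", 1, 3, "AAX")

    def test_unacetylated_lysine_rejected(self):
        with pytest.raises(ValueError, match="exactly one"):
            Peptidoform("P1", 1, 2, "AK")

    def test_doubly_acetylated_lysine_rejected(self):
        with pytest.raises(ValueError, match="exactly one"):
            Peptidoform(
                "P1", 1, 2, "AK", ((2, ACETYL_LIGHT), (2, ACETYL_HEAVY))
            )


class TestDigest:
    def test_worked_example_no_missed_cleavage(self):
        assert digest("AKRDEKR", max_missed=0, length_bounds=None) == [
            (1, 3),
            (4, 5),
            (6, 7),
        ]

    def test_worked_example_all_missed_cleavages(self):
        spans = digest("AKRDEKR", max_missed=5, length_bounds=None)
        assert len(spans) == 6  # 3 + 2 + 1 contiguous unions

    def test_no_cleavage_sites_single_span(self):
        assert digest("AAAA", max_missed=0, length_bounds=None) == [(1, 4)]

    def test_lysine_is_never_a_cleavage_site(self):
        assert digest("AKAKA", max_missed=0, length_bounds=None) == [(1, 5)]

    def test_proline_suppression(self):
        assert digest("ARPA", max_missed=0, length_bounds=None) == [(1, 4)]
        assert digest("ARPA", max_missed=0, length_bounds=None, block_proline=False) == [
            (1, 2),
            (3, 4),
        ]

    def test_gluc_e_plus_d_specificity(self):
        assert digest("ADAEA", max_missed=0, length_bounds=None, gluc_cuts="ED") == [
            (1, 2),
            (3, 4),
            (5, 5),
        ]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            digest("")

    @given(
        st.text(alphabet="ARNDEQGK", min_size=1, max_size=40),
        st.integers(min_value=0, max_value=3),
    )
    @settings(deadline=None, max_examples=100)
    def test_monotone_in_missed_cleavages(self, protein, max_missed):
        fewer = set(digest(protein, max_missed=max_missed, length_bounds=None))
        more = set(digest(protein, max_missed=max_missed + 1, length_bounds=None))
        assert fewer <= more

    @given(st.text(alphabet="AGLSK", min_size=1, max_size=10),
           st.integers(min_value=0, max_value=5))
    @settings(deadline=None, max_examples=50)
    def test_span_count_closed_form(self, middle, n_sites):
        """k internal sites + unlimited missed cleavages -> (k+1)(k+2)/2 spans."""
        protein = "R".join(["A" + middle] * (n_sites + 1))
        spans = digest(protein, max_missed=100, length_bounds=None)
        assert len(spans) == (n_sites + 1) * (n_sites + 2) // 2


class TestFragments:
    def test_b2_of_ak_light_and_heavy(self):
        light = make_peptidoform("AK", charge=1)
        heavy = make_peptidoform("AK", heavy=True, charge=1)
        assert fragment_mz(light, "b", 2) == pytest.approx(242.14991, abs=1e-5)
        assert fragment_mz(heavy, "b", 2) == pytest.approx(245.16874, abs=1e-5)

    def test_index_out_of_range(self):
        p = make_peptidoform("PEPTIDE")
        with pytest.raises(ValueError, match="outside"):
            fragment_composition(p, "b", 0)
        with pytest.raises(ValueError, match="outside"):
            fragment_composition(p, "y", 8)

    @given(st.data())
    @settings(deadline=None, max_examples=60)
    def test_by_complementarity(self, data):
        seq = data.draw(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=15))
        heavy = data.draw(st.booleans())
        p = make_peptidoform(seq, heavy=heavy)
        total = mass_of(composition_of_peptidoform(p))
        for i in range(1, len(seq)):
            b = mass_of(fragment_composition(p, "b", i))
            y = mass_of(fragment_composition(p, "y", len(seq) - i))
            assert b + y == pytest.approx(total, abs=1e-6)

    def test_light_heavy_swap_negates_mz_gap(self):
        light = make_peptidoform("GKAEKL", charge=2)
        heavy = make_peptidoform("GKAEKL", heavy=True, charge=2)
        for kind, idx in [("b", 3), ("y", 5), ("b", 5)]:
            gap = fragment_mz(heavy, kind, idx) - fragment_mz(light, kind, idx)
            swapped = fragment_mz(light, kind, idx) - fragment_mz(heavy, kind, idx)
            assert swapped == -gap


class TestPairTable:
    def test_pair_mz_gap_scales_with_labels_and_charge(self):
        p = make_peptidoform("GKAEKL")
        for fp in build_pair_table([p], charges=(1, 2, 3)):
            expected = LABEL_GAP * fp.n_acetyl_sites_covered / fp.charge
            assert fp.heavy_mz - fp.light_mz == pytest.approx(expected, abs=1e-6)

    def test_fragments_without_lysine_excluded(self):
        p = make_peptidoform("GAKAA")
        pairs = fragment_pairs(p, charges=(1,))
        # b1, b2 and y1, y2 do not cover K3 and must be absent
        covered = {(fp.fragment_kind, fp.fragment_index) for fp in pairs}
        assert ("b", 1) not in covered and ("y", 2) not in covered
        assert ("b", 3) in covered and ("y", 3) in covered

    def test_site_position_assigned_for_single_k_fragments(self):
        p = make_peptidoform("GKAEKL", start=11)
        frame = pairs_to_frame(fragment_pairs(p, charges=(1,)))
        single = frame[frame["k_acetyl"] == 1]
        assert set(single["site_position"]) == {12, 15}
        multi = frame[frame["k_acetyl"] == 2]
        assert multi["site_position"].isna().all()

    def test_correction_ratio_positive_and_below_one(self):
        p = make_peptidoform("GKAEKLNNSS")
        for fp in fragment_pairs(p, charges=(2,)):
            assert 0 < fp.correction_ratio < 1


class TestPeptidoformId:
    def test_round_trip(self):
        seq = "GKACEKL"
        mods = ((2, ACETYL_LIGHT), (4, "carbamidomethyl"), (6, ACETYL_LIGHT))
        p = Peptidoform("SYNP0001", 5, 11, seq, mods, 2)
        pid = peptidoform_id(p)
        rebuilt = parse_peptidoform_id(pid, {"SYNP0001": "AAAA" + seq + "RR"}, charge=2)
        assert rebuilt == p

    def test_unknown_protein_rejected(self):
        with pytest.raises(ValueError, match="unknown protein"):
            parse_peptidoform_id("NOPE:1-2:ac@2", {"P1": "AK"})
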