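"""Wildcard matching, class assignment, digestion, cleavage typing, masses."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from scutemark.marker_db import N_AND_C
from scutemark.peptide_tools import (
    DETERMINED,
    SEMI,
    SequenceInputError,
    UNDETERMINED,
    WATER_MONO,
    classify_peptide,
    cleavage_status,
    digest,
    match_template,
    peptide_mass,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


# -- template matching -----------------------------------------------------

def test_match_c8_against_c_template():
    res = match_template("QCQDSEVVIR", "QCPDSEVVIX")
    assert res.matched
    assert res.mismatch_positions == (3,)
    assert res.wildcard_assignments == {10: "R"}


def test_match_e1_marker_zero_mismatch():
    res = match_template("GPGLGGSFGPGGLYGYGGR", "GXGXGGSFGXGGLYGYGGR")
    assert res.matched and res.mismatch_positions == ()


def test_match_e4a_long_wildcard_assignments():
    res = match_template("AGYGGLGGYLGGYGYGGGLAGSGVSAHR",
                         "XGYGGLGGYXGGYGYGXGLXGSGVSXHR")
    assert res.matched and res.mismatch_positions == ()
    assert res.wildcard_assignments == {1: "A", 10: "L", 17: "G", 20: "A", 26: "A"}


def test_length_mismatch_fails_immediately():
    assert not match_template("GG", "GGG").matched


def test_illegal_characters_rejected():
    with pytest.raises(SequenceInputError):
        match_template("GB1", "GXG")


@settings(derandomize=True, max_examples=100)
@given(st.text(alphabet=AA + "X", min_size=1, max_size=30).filter(
    lambda t: set(t) != {"X"}))
def test_wildcard_saturation(template):
    """A template with every X replaced by G matches itself with 0 mismatches."""
    peptide = template.replace("X", "G")
    res = match_template(peptide, template)
    assert res.matched and res.mismatch_positions == ()


@settings(derandomize=True, max_examples=100)
@given(st.text(alphabet=AA, min_size=1, max_size=25), st.data())
def test_il_equivalence_symmetric(peptide, data):
    """Swapping I<->L anywhere changes nothing when il_equivalent is on."""
    i = data.draw(st.integers(0, len(peptide) - 1))
    swapped = {"I": "L", "L": "I"}.get(peptide[i], peptide[i])
    other = peptide[:i] + swapped + peptide[i + 1:]
    res_a = match_template(peptide, peptide, il_equivalent=True)
    res_b = match_template(other, peptide, il_equivalent=True)
    assert res_a.matched and res_b.matched
    assert res_b.mismatch_positions == ()


# -- class assignment ------------------------------------------------------

@pytest.mark.parametrize("peptide, expected_class, expected_mm", [
    ("QAQDSEVVIR", "C", 2),
    ("QCQDSEVVIR", "C", 1),
    ("GPGLGGSFGPGGLYGYGGR", "E1", 0),
    ("AGYGGLGGYLGGYGYGGGLAGSGVSAHR", "E4a", 0),
])
def test_printed_markers_classify_to_their_class(
        bundled_db, peptide, expected_class, expected_mm):
    res = classify_peptide(peptide, bundled_db)
    assert res.class_id == expected_class
    assert res.mismatch_count == expected_mm


def test_unclassifiable_peptide_gets_none(bundled_db):
    res = classify_peptide("G" * 50, bundled_db)
    assert res.class_id is None and res.candidates == ()


# -- digestion -------------------------------------------------------------

def test_specific_digest_worked_example():
    peps = digest("MKGYRAAGR", mode="specific", missed_cleavages=1, min_len=2)
    assert {p.sequence for p in peps} == {"MK", "GYR", "AAGR", "MKGYR", "GYRAAGR"}


def test_protein_without_cut_sites_yields_itself():
    peps = digest("MGGAGGAG", mode="specific", min_len=2)
    assert {p.sequence for p in peps} == {"MGGAGGAG"}
    (p,) = peps
    assert p.prev_residue == "-" and p.next_residue == "-"


def _oracle_digest(protein, mode, missed, min_len, max_len, before_p):
    """Independent brute force: every substring, filtered by junction rules."""
    n = len(protein)

    def cut(pos):
        return (0 < pos < n and protein[pos - 1] in "KR"
                and (before_p or protein[pos] != "P"))

    out = set()
    for s in range(n):
        for e in range(s + 1, n + 1):
            if not min_len <= e - s <= max_len:
                continue
            if sum(cut(p) for p in range(s + 1, e)) > missed:
                continue
            n_ok = s == 0 or cut(s)
            c_ok = e == n or cut(e)
            if mode == "specific" and not (n_ok and c_ok):
                continue
            if mode == "semispecific" and not (n_ok or c_ok):
                continue
            out.add((protein[s:e], s + 1, e))
    return out


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.text(alphabet=AA, min_size=1, max_size=60),
       st.sampled_from(["specific", "semispecific"]),
       st.integers(0, 2), st.booleans())
def test_digest_matches_bruteforce_oracle(protein, mode, missed, before_p):
    got = digest(protein, mode=mode, missed_cleavages=missed, min_len=2,
                 max_len=45, cleave_before_proline=before_p)
    assert {(p.sequence, p.start, p.end) for p in got} \
        == _oracle_digest(protein, mode, missed, 2, 45, before_p)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.text(alphabet=AA, min_size=6, max_size=50))
def test_semispecific_superset_of_specific(protein):
    spec = {(p.sequence, p.start, p.end) for p in digest(protein, "specific")}
    semi = {(p.sequence, p.start, p.end) for p in digest(protein, "semispecific")}
    assert spec <= semi


def test_digest_coordinates_and_missed_counts():
    peps = {p.sequence: p for p in
            digest("MKGYRAAGR", mode="specific", missed_cleavages=1, min_len=2)}
    assert (peps["GYRAAGR"].start, peps["GYRAAGR"].end) == (3, 9)
    assert peps["GYRAAGR"].n_missed == 1
    assert peps["AAGR"].prev_residue == "R"
    assert peps["MK"].specificity == "fully_tryptic"


# -- cleavage typing -------------------------------------------------------

def test_full_marker_both_tryptic_is_determined(bundled_db):
    m = bundled_db.marker_by_id("C-2")
    t = bundled_db.template_by_id("C")
    assert t.tryptic_termini == N_AND_C
    assert cleavage_status(m.sequence, m, t) == DETERMINED


def test_n_trimmed_marker_is_semi(bundled_db):
    m = bundled_db.marker_by_id("C-2")
    t = bundled_db.template_by_id("C")
    assert cleavage_status(m.sequence[2:], m, t) == SEMI


def test_double_trimmed_marker_is_undetermined(bundled_db):
    m = bundled_db.marker_by_id("E1-7")
    t = bundled_db.template_by_id("E1")
    assert cleavage_status(m.sequence[2:-2], m, t) == UNDETERMINED


def test_tryptic_flank_rescues_n_terminus(bundled_db):
    m = bundled_db.marker_by_id("C-2")
    t = bundled_db.template_by_id("C")
    assert cleavage_status(m.sequence[2:], m, t, flanks=("R", None)) == DETERMINED


def test_unalignable_peptide_is_undetermined(bundled_db):
    m = bundled_db.marker_by_id("C-2")
    t = bundled_db.template_by_id("C")
    assert cleavage_status("WWWWWW", m, t) == UNDETERMINED


# -- masses ----------------------------------------------------------------

def test_diglycine_mass():
    assert math.isclose(peptide_mass("GG"), 132.0535, abs_tol=1e-3)


def test_empty_sequence_rejected():
    with pytest.raises(SequenceInputError):
        peptide_mass("")


def test_modification_position_out_of_range():
    with pytest.raises(SequenceInputError):
        peptide_mass("GG", [(3, "Oxidation")])


def test_carbamidomethyl_additivity():
    base = peptide_mass("QCQDSEVVIR")
    assert math.isclose(peptide_mass("QCQDSEVVIR", [(2, "Carbamidomethyl")]),
                        base + 57.02146, abs_tol=1e-6)


@settings(derandomize=True, max_examples=100)
@given(st.text(alphabet=AA, min_size=1, max_size=20),
       st.text(alphabet=AA, min_size=1, max_size=20))
def test_mass_additivity_over_concatenation(s1, s2):
    assert math.isclose(peptide_mass(s1 + s2),
                        peptide_mass(s1) + peptide_mass(s2) - WATER_MONO,
                        abs_tol=1e-9)
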