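"""Sequence-level primitives for CBP marker analysis.

Wildcard template matching (``X`` matches any residue, optional I/L
equivalence), class assignment of peptides against the A-F templates,
in-silico (semi)specific tryptic digestion, typing of a PSM's cleavage
status against its marker's canonical boundaries, and monoisotopic peptide
masses.  Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from pyteomics import mass as _pt_mass

from .marker_db import (
    AA_LETTERS,
    CLASS_ORDER,
    C_ONLY,
    N_AND_C,
    N_ONLY,
    Marker,
    MarkerClassTemplate,
    MarkerDatabase,
)

logger = logging.getLogger(__name__)

#: Flank sentinel marking a protein terminus (no flanking residue).
TERMINUS = "-"

#: Named modification monoisotopic mass shifts (Da).
MOD_MASSES: dict[str, float] = {
    "Carbamidomethyl": 57.02146,
    "Oxidation": 15.99491,
    "Dioxidation": 31.98983,
    "Phospho": 79.96633,
    "Deamidation": 0.98402,
    "Pyroglutamate": -17.02655,
}

WATER_MONO = 18.0105646863

DETERMINED = "determined"
SEMI = "semi"
UNDETERMINED = "undetermined"


class SequenceInputError(ValueError):
    """Illegal residue letters or out-of-range positions."""


def _check_sequence(s: str, what: str = "peptide", extra: str = "") -> None:
    if not s:
        raise SequenceInputError(f"empty {what}")
    bad = set(s) - AA_LETTERS - set(extra)
    if bad:
        raise SequenceInputError(f"{what} contains illegal characters {sorted(bad)}")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one peptide against one wildcard template."""

    matched: bool
    mismatch_positions: tuple[int, ...] = ()
    wildcard_assignments: dict[int, str] = field(default_factory=dict)


def match_template(peptide: str, template: str, il_equivalent: bool = True,
                   max_mismatch: int = 2) -> MatchResult:
    """Match ``peptide`` against a wildcard ``template`` position by position.

    ``X`` in the template matches any residue (the observed residue is
    reported in ``wildcard_assignments``); with ``il_equivalent`` the isomers
    leucine and isoleucine are interchangeable at non-wildcard positions.
    A length difference fails immediately.
    """
    _check_sequence(peptide)
    _check_sequence(template, "template", extra="X")
    if len(peptide) != len(template):
        return MatchResult(False)
    mismatches: list[int] = []
    wild: dict[int, str] = {}
    for i, (p, t) in enumerate(zip(peptide, template), start=1):
        if t == "X":
            wild[i] = p
        elif p != t and not (il_equivalent and {p, t} <= {"I", "L"}):
            mismatches.append(i)
    return MatchResult(len(mismatches) <= max_mismatch, tuple(mismatches), wild)


@dataclass(frozen=True)
class ClassAssignment:
    """Template-inferred class of a peptide (curated labels take precedence)."""

    class_id: str | None
    mismatch_count: int | None
    ambiguous: bool
    candidates: tuple[tuple[str, int], ...]  # (reporting class, mismatches)


def classify_peptide(peptide: str, db: MarkerDatabase, max_mismatch: int = 2,
                     il_equivalent: bool = True) -> ClassAssignment:
    """Assign a peptide to the minimum-mismatch class among length-compatible
    templates.

    Ties on mismatch count prefer the longer template, then the fixed class
    order A..F; a tie between distinct reporting classes sets ``ambiguous``.
    Unclassifiable peptides get class ``None``.
    """
    hits: list[tuple[int, int, int, str]] = []  # (mm, -len, class order, class)
    for t in db.templates:
        if t.length != len(peptide):
            continue
        res = match_template(peptide, t.template, il_equivalent, max_mismatch)
        if res.matched:
            hits.append((len(res.mismatch_positions), -t.length,
                         CLASS_ORDER.index(t.reporting_class), t.reporting_class))
    if not hits:
        return ClassAssignment(None, None, False, ())
    hits.sort()
    best_mm = hits[0][0]
    candidates = tuple(dict.fromkeys((h[3], h[0]) for h in hits))
    tied = {h[3] for h in hits if h[0] == best_mm}
    return ClassAssignment(hits[0][3], best_mm, len(tied) > 1, candidates)


FULLY_TRYPTIC = "fully_tryptic"
SEMI_N = "semi_N"   # only the N-terminal junction is tryptic
SEMI_C = "semi_C"   # only the C-terminal junction is tryptic
NONSPECIFIC = "nonspecific"


@dataclass(frozen=True)
class DigestPeptide:
    """One in-silico digest product with 1-based inclusive coordinates."""

    sequence: str
    start: int
    end: int
    prev_residue: str
    next_residue: str
    n_missed: int
    specificity: str


def _cut_ok(protein: str, pos: int, before_proline: bool) -> bool:
    """Is there a tryptic cut between 0-based positions pos-1 and pos?"""
    if pos <= 0 or pos > len(protein):
        return False
    if protein[pos - 1] not in "KR":
        return False
    return before_proline or pos == len(protein) or protein[pos] != "P"


def digest(protein: str, mode: str = "semispecific", missed_cleavages: int = 1,
           min_len: int = 6, max_len: int = 45,
           cleave_before_proline: bool = True) -> set[DigestPeptide]:
    """In-silico trypsin digest (cleave after K/R).

    ``mode="specific"`` yields fully tryptic peptides only; ``"semispecific"``
    additionally yields peptides with exactly one tryptic terminus (protein
    termini count as tryptic boundaries).  ``cleave_before_proline=False``
    enables the no-cut-before-proline trypsin variant.
    """
    _check_sequence(protein, "protein")
    if mode not in ("specific", "semispecific"):
        raise ValueError(f"unknown digest mode {mode!r}")
    n = len(protein)
    sites = [p for p in range(1, n) if _cut_ok(protein, p, cleave_before_proline)]
    boundaries = [0, *sites, n]
    site_set = set(sites)

    def n_internal(s: int, e: int) -> int:
        return sum(1 for p in sites if s < p < e)

    out: set[DigestPeptide] = set()

    def emit(s: int, e: int) -> None:
        if not (min_len <= e - s <= max_len):
            return
        miss = n_internal(s, e)
        if miss > missed_cleavages:
            return
        n_tryptic = s == 0 or s in site_set
        c_tryptic = e == n or e in site_set
        spec = (FULLY_TRYPTIC if n_tryptic and c_tryptic
                else SEMI_N if n_tryptic else SEMI_C if c_tryptic else NONSPECIFIC)
        if mode == "specific" and spec != FULLY_TRYPTIC:
            return
        if spec == NONSPECIFIC:
            return
        out.add(DigestPeptide(
            sequence=protein[s:e], start=s + 1, end=e,
            prev_residue=protein[s - 1] if s > 0 else TERMINUS,
            next_residue=protein[e] if e < n else TERMINUS,
            n_missed=miss, specificity=spec))

    if mode == "specific":
        for i, s in enumerate(boundaries[:-1]):
            for e in boundaries[i + 1:]:
                emit(s, e)
    else:
        for s in boundaries[:-1]:
            for e in range(s + 1, n + 1):
                emit(s, e)
        for e in boundaries[1:]:
            for s in range(0, e):
                emit(s, e)
    return out


def align_to_marker(peptide: str, marker_sequence: str, max_mismatch: int = 2,
                    ) -> int | None:
    """0-based offset of the unique best alignment of ``peptide`` within the
    marker, or None when absent or ambiguous.

    Exact substring search first; if absent, a sliding scan allowing up to
    ``max_mismatch`` substitutions.  Multiple equally good offsets -> None.
    """
    if len(peptide) > len(marker_sequence):
        return None
    exact = []
    pos = marker_sequence.find(peptide)
    while pos != -1 and len(exact) < 2:
        exact.append(pos)
        pos = marker_sequence.find(peptide, pos + 1)
    if len(exact) == 1:
        return exact[0]
    if len(exact) > 1:
        return None
    scored: list[tuple[int, int]] = []
    for i in range(len(marker_sequence) - len(peptide) + 1):
        mm = sum(1 for a, b in zip(peptide, marker_sequence[i:i + len(peptide)])
                 if a != b)
        if mm <= max_mismatch:
            scored.append((mm, i))
    if not scored:
        return None
    scored.sort()
    if len(scored) > 1 and scored[0][0] == scored[1][0]:
        return None
    return scored[0][1]


def cleavage_status(psm_peptide: str, marker: Marker,
                    template: MarkerClassTemplate,
                    flanks: tuple[str | None, str | None] | None = None) -> str:
    """Type a PSM's termini against its marker's canonical boundaries.

    A terminus is *determined* when it coincides with the marker boundary on a
    side the template marks as tryptic, when the flanking residue shows a
    genuine tryptic junction (preceded by K/R for the N side; the peptide
    itself ending in K/R for the C side), or when it sits at a protein
    terminus (flank sentinel ``-``).  Both ends determined -> ``determined``;
    one -> ``semi``; neither, or no unique alignment -> ``undetermined``.
    """
    _check_sequence(psm_peptide)
    offset = align_to_marker(psm_peptide, marker.sequence)
    if offset is None:
        logger.debug("peptide %s not uniquely alignable to marker %s",
                     psm_peptide, marker.marker_id)
        return UNDETERMINED
    prev_res, next_res = flanks if flanks is not None else (None, None)

    n_at_boundary = offset == 0
    c_at_boundary = offset + len(psm_peptide) == len(marker.sequence)
    n_tryptic_side = template.tryptic_termini in (N_ONLY, N_AND_C)
    c_tryptic_side = template.tryptic_termini in (C_ONLY, N_AND_C)

    n_det = (n_at_boundary and n_tryptic_side) or prev_res in ("K", "R") \
        or prev_res == TERMINUS
    c_det = (c_at_boundary and c_tryptic_side) or psm_peptide[-1] in "KR" \
        or next_res == TERMINUS
    if n_det and c_det:
        return DETERMINED
    if n_det or c_det:
        return SEMI
    return UNDETERMINED


def peptide_mass(sequence: str,
                 modifications: list[tuple[int, float | str]] | None = None,
                 ) -> float:
    """Monoisotopic peptide mass in Da: residue masses + water + mod deltas.

    Modifications are ``(1-based position, delta)`` pairs where the delta is
    either a mass shift in Da or a named shift from :data:`MOD_MASSES`.
    """
    _check_sequence(sequence)
    total = sum(_pt_mass.std_aa_mass[a] for a in sequence) + WATER_MONO
    for pos, delta in modifications or []:
        if not 1 <= pos <= len(sequence):
            raise SequenceInputError(
                f"modification position {pos} outside 1..{len(sequence)}")
        if isinstance(delta, str):
            try:
                delta = MOD_MASSES[delta]
            except KeyError as exc:
                raise SequenceInputError(f"unknown modification {delta!r}") from exc
        total += delta
    return total
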