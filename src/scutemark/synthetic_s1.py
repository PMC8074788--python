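"""Synthetic stand-in for the full validated-marker table (187 markers).

The complete per-species validated marker list is not available for
redistribution with this package.  This module therefore constructs a
*synthetic* marker table whose species-validation patterns and class
composition satisfy every published summary count, so that the set-algebra
and import machinery can be exercised end-to-end at realistic scale:

* 187 markers in total; class counts A=34, B=53, E4a=47; no class-D markers
  (class D was reported "data not shown" and not used for differentiation);
* 33 markers validated in all five species; 56 in all four genera;
* species-unique counts: E. imbricata 20, C. mydas 19, C. caretta 17,
  L. olivacea 15, L. kempii 2;
* 21 markers exclusively shared by E. imbricata + C. caretta + Lepidochelys,
  7 by C. mydas + C. caretta + Lepidochelys;
* 124 markers validated in E. imbricata in total.

Sequences are generated deterministically from the class wildcard templates
(wildcards filled from a fixed residue rotation, never K/R at internal
positions so every marker stays a clean tryptic peptide).  The five printed
markers (C-2, C-8, E2c-4, E4a-19.1, E1-7) and the E. imbricata-unique A-15
(S3->E3) keep their published sequences and identities.  Everything else is
synthetic: individual sequences carry no biological meaning.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import pandas as pd

from .marker_db import (
    CARETTA_CARETTA,
    CHELONIA_MYDAS,
    ERETMOCHELYS_IMBRICATA,
    LEPIDOCHELYS_KEMPII,
    LEPIDOCHELYS_OLIVACEA,
    SPECIES,
    BUNDLED_TEMPLATES,
    Marker,
    MarkerDatabase,
)

CM, CC, EI, LO, LK = (CHELONIA_MYDAS, CARETTA_CARETTA, ERETMOCHELYS_IMBRICATA,
                      LEPIDOCHELYS_OLIVACEA, LEPIDOCHELYS_KEMPII)

# Validation patterns (which species a marker is validated in) and the class
# composition of each pattern bucket.  Bucket sizes are chosen so that all the
# published set-algebra totals above hold exactly.
_BUCKETS: list[tuple[frozenset[str], dict[str, int]]] = [
    (frozenset({CM, CC, EI, LO, LK}),
     {"F": 2, "E4b": 2, "C": 4, "E1": 6, "E2c": 2, "E2d": 3, "E3": 5, "A": 9}),
    (frozenset({CM, CC, EI, LO}), {"F": 1, "E1": 2, "A": 5, "B": 7}),
    (frozenset({CM, CC, EI, LK}), {"F": 1, "A": 3, "B": 4}),
    (frozenset({CC, EI, LO, LK}),
     {"E4b": 1, "E2c": 2, "E2d": 1, "E2b": 2, "B": 3, "E4a": 3}),
    (frozenset({CC, EI, LO}), {"E2b": 1, "B": 3, "E4a": 2}),
    (frozenset({CC, EI, LK}), {"B": 1, "E4a": 2}),
    (frozenset({CM, CC, LO, LK}), {"A": 2, "B": 2}),
    (frozenset({CM, CC, LO}), {"A": 1, "B": 2}),
    (frozenset({EI}), {"E4b": 1, "C": 2, "E1": 1, "E2c": 1, "A": 1, "B": 2, "E4a": 12}),
    (frozenset({CM}), {"E2a": 2, "C": 3, "A": 5, "B": 8, "E4a": 1}),
    (frozenset({CC}), {"E4b": 1, "A": 2, "B": 6, "E4a": 8}),
    (frozenset({LO}), {"E4b": 1, "E2b": 2, "B": 3, "E4a": 9}),
    (frozenset({LK}), {"E4b": 2}),
    (frozenset({CC, EI}), {"A": 2, "B": 5, "E4a": 3}),
    (frozenset({EI, LO}), {"B": 2, "E4a": 4}),
    (frozenset({EI, LK}), {"B": 1, "E4a": 2}),
    (frozenset({CM, EI}), {"A": 4, "B": 4}),
    (frozenset({CC, LO}), {"E2b": 2, "E4a": 1}),
]

# Published sequences kept verbatim, pinned to their bucket (index into
# _BUCKETS) and consuming one slot of that bucket's class allocation.
_PINNED: list[tuple[str, str, str, int]] = [
    ("C-2", "C", "QAQDSEVVIR", 8),
    ("C-8", "C", "QCQDSEVVIR", 8),
    ("E2c-4", "E2c", "YGGLHGLGR", 8),
    ("E4a-19.1", "E4a_long", "AGYGGLGGYLGGYGYGGGLAGSGVSAHR", 8),
    ("E1-7", "E1", "GPGLGGSFGPGGLYGYGGR", 8),
    ("A-15", "A", "GGEGLGYPEGGVAR", 8),  # S3->E3 on a wildcard-filled A template
]

_INTERNAL_FILL = "GASLVYFITQHENMDW"  # no K/R inside a tryptic peptide
_TERMINAL_FILL = "RK"                 # C-terminal wildcard: tryptic residue


def _sequence_stream(template: str, reserved: set[str]):
    """Deterministic stream of unique concrete sequences for one template.

    Wildcards are filled from a fixed rotation (terminal position from K/R);
    once fill combinations run out, one internal non-wildcard position is
    substituted as real markers do.
    """
    xpos = [i for i, c in enumerate(template) if c == "X"]
    alphabets = [_TERMINAL_FILL if i == len(template) - 1 else _INTERNAL_FILL
                 for i in xpos]
    produced: list[str] = []
    for combo in itertools.product(*alphabets):
        seq = list(template)
        for i, res in zip(xpos, combo):
            seq[i] = res
        s = "".join(seq)
        if s in reserved:
            continue
        reserved.add(s)
        produced.append(s)
        yield s
    # fill combinations exhausted: mutate one internal fixed position
    fixed = [i for i, c in enumerate(template) if c != "X" and i != len(template) - 1]
    for j, repl, base in itertools.product(fixed, _INTERNAL_FILL, list(produced)):
        if base[j] == repl:
            continue
        s = base[:j] + repl + base[j + 1:]
        if s in reserved:
            continue
        reserved.add(s)
        yield s


def _template_string(templates, template_id: str) -> str:
    for t in templates:
        if t.class_id == template_id:
            return t.template
    raise KeyError(template_id)


def build_markers() -> list[Marker]:
    """Construct the 187 synthetic markers (deterministic, no RNG)."""
    templates = BUNDLED_TEMPLATES
    reserved = {seq for _, _, seq, _ in _PINNED}
    streams = {
        tid: _sequence_stream(_template_string(templates, tid), reserved)
        for tid in ("A", "B", "C", "E1", "E2a", "E2b", "E2c", "E2d", "E3",
                    "E4a_short", "E4a_long", "E4b", "F")
    }
    pinned_by_bucket: dict[int, list[tuple[str, str, str]]] = {}
    for mid, cid, seq, bucket in _PINNED:
        pinned_by_bucket.setdefault(bucket, []).append((mid, cid, seq))
    reserved_ids = {mid for mid, _, _, _ in _PINNED}

    counters = {c: 0 for c in
                ("A", "B", "C", "E1", "E2a", "E2b", "E2c", "E2d", "E3",
                 "E4a", "E4b", "F")}

    def next_id(reporting: str) -> str:
        while True:
            counters[reporting] += 1
            mid = f"{reporting}-{counters[reporting]}"
            if mid not in reserved_ids:
                return mid

    markers: list[Marker] = []
    e4a_index = 0
    for bucket_idx, (species_set, class_counts) in enumerate(_BUCKETS):
        pinned_list = pinned_by_bucket.get(bucket_idx, [])
        for reporting, count in class_counts.items():
            taken = [p for p in pinned_list
                     if (p[1] if not p[1].startswith("E4a") else "E4a") == reporting
                     or p[1] == reporting]
            for mid, cid, seq in taken:
                markers.append(Marker(mid, cid, seq, species_set,
                                      notes="published sequence"))
            for _ in range(count - len(taken)):
                if reporting == "E4a":
                    # mix short and long forms; the short form never occurs in
                    # C. mydas, so CM-containing buckets only get the long one
                    short_ok = CM not in species_set
                    use_short = short_ok and e4a_index % 3 == 2
                    e4a_index += 1
                    tid = "E4a_short" if use_short else "E4a_long"
                else:
                    tid = reporting
                seq = next(streams[tid])
                markers.append(Marker(next_id(reporting), tid, seq, species_set,
                                      notes="synthetic"))
    return markers


def build_table() -> pd.DataFrame:
    """The synthetic supplement as a metadata-TSV-dialect DataFrame."""
    rows = []
    for m in build_markers():
        row: dict[str, object] = {
            "marker_id": m.marker_id, "class_id": m.class_id, "sequence": m.sequence,
        }
        for sp in SPECIES:
            row[sp] = int(sp in m.species_validated)
        rows.append(row)
    return pd.DataFrame(rows, columns=["marker_id", "class_id", "sequence", *SPECIES])


def write_table(path: str | Path) -> None:
    build_table().to_csv(path, sep="\t", index=False)


def enriched_database() -> MarkerDatabase:
    """Bundled database merged with the full synthetic supplement."""
    from .marker_db import bundled_database

    db = bundled_database()
    incoming = {m.marker_id: m for m in build_markers()}
    merged = []
    for m in db.markers:
        merged.append(incoming.pop(m.marker_id, m))
    merged.extend(incoming.values())
    return MarkerDatabase(templates=list(db.templates), markers=merged,
                          species=list(db.species), genus_map=dict(db.genus_map))
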