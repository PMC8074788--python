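"""Marker-set algebra over species/genera and species assignment of samples.

A sample's species call rests on two kinds of evidence: the *fraction* of
each species' validated marker repertoire detected in the sample, and the
detection of markers *unique* to a species.  Class D markers are excluded
from differentiation by default (highly conserved, many random cleavages);
class E1 can be excluded optionally (unreliable tryptic context).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .marker_db import MarkerDatabase

logger = logging.getLogger(__name__)

INCONCLUSIVE = "inconclusive"
DEFAULT_EXCLUDED_CLASSES = frozenset({"D"})


def unique_markers(db: MarkerDatabase, level: str = "species",
                   ) -> dict[str, set[str]]:
    """Marker ids validated in exactly one label at the given level.

    At species level a marker is unique to S when validated in S and no
    other species; at genus level when all its validated species fall in one
    genus.
    """
    if level not in ("species", "genus"):
        raise ValueError(f"unknown level {level!r}")
    if level == "species":
        out: dict[str, set[str]] = {sp: set() for sp in db.species}
        for m in db.markers:
            if len(m.species_validated) == 1:
                (sp,) = m.species_validated
                out[sp].add(m.marker_id)
        return out
    out = {g: set() for g in db.genera()}
    for m in db.markers:
        genera = {db.genus_map[sp] for sp in m.species_validated}
        if len(genera) == 1:
            (g,) = genera
            out[g].add(m.marker_id)
    return out


def shared_markers(db: MarkerDatabase, labels: set[str],
                   exclusive: bool = False) -> set[str]:
    """Markers validated in every label of ``labels`` (species or genus names).

    A genus label is covered when the marker is validated in at least one of
    the genus' species.  With ``exclusive=True`` the marker's validated
    genera must equal exactly the genera implied by ``labels``.
    """
    genera = set(db.genera())
    target_genera: set[str] = set()
    for lab in labels:
        if lab in db.species:
            target_genera.add(db.genus_map[lab])
        elif lab in genera:
            target_genera.add(lab)
        else:
            raise ValueError(f"unknown species/genus label {lab!r}")

    def covers(m, lab: str) -> bool:
        if lab in db.species:
            return lab in m.species_validated
        return any(sp in m.species_validated for sp in db.species_of_genus(lab))

    out = set()
    for m in db.markers:
        if not all(covers(m, lab) for lab in labels):
            continue
        if exclusive:
            m_genera = {db.genus_map[sp] for sp in m.species_validated}
            if m_genera != target_genera:
                continue
        out.add(m.marker_id)
    return out


@dataclass
class SpeciesCall:
    """Ranked per-species marker-match evidence and the final call."""

    fractions: dict[str, float]           # percent of repertoire detected
    detected_counts: dict[str, int]
    total_counts: dict[str, int]
    unique_markers_hit: dict[str, list[str]]
    call: str                             # species label or "inconclusive"
    candidates: list[str] = field(default_factory=list)
    excluded_classes: frozenset[str] = DEFAULT_EXCLUDED_CLASSES

    def to_json(self, **kwargs) -> str:
        payload = {
            "call": self.call,
            "candidates": self.candidates,
            "fractions_percent": {k: round(v, 1) for k, v in self.fractions.items()},
            "detected_counts": self.detected_counts,
            "total_counts": self.total_counts,
            "unique_markers_hit": self.unique_markers_hit,
            "excluded_classes": sorted(self.excluded_classes),
        }
        return json.dumps(payload, indent=2, sort_keys=True, **kwargs)


def assign_species(detections: set[str], db: MarkerDatabase,
                   exclude_classes: frozenset[str] = DEFAULT_EXCLUDED_CLASSES,
                   ) -> SpeciesCall:
    """Call the species of a sample from its set of detected marker ids.

    Per species the match fraction is 100 x |detections ∩ repertoire| /
    |repertoire| with the excluded classes removed from both sides.  The
    call is anchored in unique-marker evidence: among the species with at
    least one detected unique marker, the one with the maximal fraction is
    called.  No unique support at all, or a fraction tie among supported
    species, yields ``inconclusive``.  Raw fraction ranking alone is not
    trusted because a species whose repertoire nests inside another's can
    out-rank it on fractions without any discriminating marker.
    """
    known = set(db.marker_ids())
    detections = set(detections)
    unknown = detections - known
    if unknown:
        logger.debug("ignoring %d unknown marker ids in detections", len(unknown))
        detections &= known
    excluded_ids = {m.marker_id for m in db.markers
                    if m.reporting_class in exclude_classes}
    detections -= excluded_ids

    uniques = unique_markers(db, level="species")
    fractions: dict[str, float] = {}
    detected_counts: dict[str, int] = {}
    total_counts: dict[str, int] = {}
    unique_hit: dict[str, list[str]] = {}
    for sp in db.species:
        repertoire = db.markers_for_species(sp, exclude_classes=exclude_classes)
        total_counts[sp] = len(repertoire)
        hit = detections & repertoire
        detected_counts[sp] = len(hit)
        fractions[sp] = 100.0 * len(hit) / len(repertoire) if repertoire else 0.0
        unique_hit[sp] = sorted(detections & (uniques[sp] - excluded_ids))

    if not detections:
        return SpeciesCall(fractions, detected_counts, total_counts, unique_hit,
                           INCONCLUSIVE, [], frozenset(exclude_classes))
    supported = [sp for sp in db.species if unique_hit[sp]]
    if not supported:
        best = max(fractions.values())
        call = INCONCLUSIVE
        candidates = [sp for sp in db.species if fractions[sp] == best]
    else:
        best = max(fractions[sp] for sp in supported)
        leaders = [sp for sp in supported if fractions[sp] == best]
        call = leaders[0] if len(leaders) == 1 else INCONCLUSIVE
        candidates = leaders
    return SpeciesCall(fractions, detected_counts, total_counts, unique_hit,
                       call, candidates, frozenset(exclude_classes))
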