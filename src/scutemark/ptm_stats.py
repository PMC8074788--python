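"""Site-occupancy statistics for oxidative modifications and phospho motifs.

Oxidation (+15.99 Da) and dioxidation (+31.99 Da) are diagenesis/handling
indicators counted on the four oxidisable residues P, Y, H and W.  The
denominator is the number of *potential* sites: for each marker, the count
of P/Y/H/W residues in its sequence multiplied by the number of (filtered)
PSMs detected for that marker.  The numerator counts site-level modified
observations: a PSM with two oxidised residues contributes two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .marker_db import MarkerDatabase
from .psm_model import Cohort

logger = logging.getLogger(__name__)

OXIDIZABLE = set("PYHW")
DEFAULT_CLASSES = frozenset({"A", "B", "E4a"})


def potential_sites(sequence: str) -> int:
    """Number of oxidisable residues (P, Y, H, W) in a sequence."""
    return sum(1 for a in sequence if a in OXIDIZABLE)


@dataclass(frozen=True)
class OxidationReport:
    """Oxidation/dioxidation site occupancy for one group of specimens."""

    group: str
    percent_oxidation: float
    percent_dioxidation: float
    potential_sites: int
    observed_ox_sites: int
    observed_diox_sites: int
    stdev_oxidation: float
    stdev_dioxidation: float
    n_specimens: int


def _group_key(run, db: MarkerDatabase, group_by: str) -> str | None:
    if group_by == "sample":
        return run.sample_id
    if run.species_truth is None:
        return None
    if group_by == "species":
        return run.species_truth
    if group_by == "genus":
        return db.genus_map.get(run.species_truth, run.species_truth)
    raise ValueError(f"unknown group_by {group_by!r}")


def oxidation_percentages(cohort: Cohort, db: MarkerDatabase,
                          classes: frozenset[str] = DEFAULT_CLASSES,
                          group_by: str = "genus",
                          psm_level: bool = False) -> list[OxidationReport]:
    """Percentage of potential P/Y/H/W sites observed (di)oxidised, per group.

    Restricted to markers of the given reporting classes (default A, B, E4a,
    which carry most oxidative modifications).  Oxidation observed on other
    residues (e.g. methionine) is excluded from numerator and denominator and
    logged.  ``psm_level=True`` counts at most one (di)oxidation observation
    per PSM instead of per site.  Standard deviations are across specimens.
    """
    seq_by_marker = {m.marker_id: m.sequence for m in db.markers
                     if m.reporting_class in classes}
    per_specimen: dict[str, list[tuple[int, int, int]]] = {}
    skipped_off_target = 0
    for run in cohort:
        group = _group_key(run, db, group_by)
        if group is None:
            continue
        pot = ox = diox = 0
        for p in run.psms:
            seq = seq_by_marker.get(p.assigned_marker_id)
            if seq is None:
                continue
            pot += potential_sites(seq)
            n_ox = n_diox = 0
            for pos, name, _ in p.modifications:
                if name not in ("Oxidation", "Dioxidation"):
                    continue
                if p.peptide[pos - 1] not in OXIDIZABLE:
                    skipped_off_target += 1
                    continue
                if name == "Oxidation":
                    n_ox += 1
                else:
                    n_diox += 1
            if psm_level:
                n_ox, n_diox = min(n_ox, 1), min(n_diox, 1)
            ox += n_ox
            diox += n_diox
        per_specimen.setdefault(group, []).append((pot, ox, diox))
    if skipped_off_target:
        logger.info("excluded %d oxidative observations on non-P/Y/H/W residues",
                    skipped_off_target)

    reports = []
    for group, rows in per_specimen.items():
        pot = sum(r[0] for r in rows)
        ox = sum(r[1] for r in rows)
        diox = sum(r[2] for r in rows)
        if pot == 0:
            continue
        pct = [(100.0 * o / p_, 100.0 * d / p_) for p_, o, d in rows if p_ > 0]
        sd_ox = float(np.std([x[0] for x in pct], ddof=1)) if len(pct) > 1 else 0.0
        sd_dx = float(np.std([x[1] for x in pct], ddof=1)) if len(pct) > 1 else 0.0
        reports.append(OxidationReport(
            group=group,
            percent_oxidation=100.0 * ox / pot,
            percent_dioxidation=100.0 * diox / pot,
            potential_sites=pot, observed_ox_sites=ox, observed_diox_sites=diox,
            stdev_oxidation=sd_ox, stdev_dioxidation=sd_dx,
            n_specimens=len(rows)))
    return reports


@dataclass
class PhosphoSummary:
    """Phospho-serine counts by following residue and C-terminal context."""

    by_context: dict[str, int]        # keys always SAHR, SCHR, other
    by_following: dict[str, int]      # residue after the phospho-S ("-" = C-term)

    def total(self) -> int:
        return sum(self.by_context.values())


def phospho_motif_summary(cohort: Cohort) -> PhosphoSummary:
    """Tally phosphorylation events on serine by sequence context.

    The diagnostic contrast is the C-terminal ``GSGVSXHR`` tag of the E4a
    region: serines in a ``SAHR`` suffix are frequently phosphorylated while
    serines in ``SCHR`` are not.
    """
    by_context = {"SAHR": 0, "SCHR": 0, "other": 0}
    by_following: dict[str, int] = {}
    for run in cohort:
        for p in run.psms:
            for pos, name, _ in p.modifications:
                if name != "Phospho" or p.peptide[pos - 1] != "S":
                    continue
                window = p.peptide[pos - 1:pos + 3]
                context = window if window in ("SAHR", "SCHR") else "other"
                by_context[context] += 1
                following = p.peptide[pos] if pos < len(p.peptide) else "-"
                by_following[following] = by_following.get(following, 0) + 1
    return PhosphoSummary(by_context, by_following)
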