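"""PSM ingestion, per-marker MAD score cut-offs, detection matrices and
cleavage-degradation summaries.

A PSM (peptide-spectrum match) carries a peptide sequence, a -10lgP score
(higher is more confident) and a modification list.  Marker validation
removes score outliers with a per-marker cut-off equal to the score median
minus the (unscaled) median absolute deviation, computed from the pooled
carbamidomethyl-only/unmodified PSMs of that marker across the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .marker_db import MarkerDatabase
from .peptide_tools import (
    MOD_MASSES,
    UNDETERMINED,
    align_to_marker,
    classify_peptide,
    cleavage_status,
)


class SchemaError(ValueError):
    """A PSM table is missing required columns or has malformed rows."""


@dataclass(frozen=True)
class PSM:
    """One peptide-spectrum match."""

    sample_id: str
    peptide: str
    score: float
    modifications: tuple[tuple[int, str, float], ...] = ()
    prev_residue: str | None = None
    next_residue: str | None = None
    assigned_marker_id: str | None = None
    assigned_class: str | None = None
    cleavage: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise SchemaError(f"non-finite score for peptide {self.peptide}")
        for pos, name, _ in self.modifications:
            if not 1 <= pos <= len(self.peptide):
                raise SchemaError(
                    f"modification {name}@{pos} outside peptide {self.peptide}")

    def mod_names(self) -> set[str]:
        return {name for _, name, _ in self.modifications}


@dataclass
class SampleRun:
    """All pooled PSMs of one specimen/sample."""

    sample_id: str
    psms: list[PSM] = field(default_factory=list)
    species_truth: str | None = None
    provenance: str = ""


Cohort = list[SampleRun]


def _parse_mods(text: str, line_no: int) -> tuple[tuple[int, str, float], ...]:
    """Parse the ``Name@pos;Name@pos`` modification dialect."""
    text = (text or "").strip()
    if not text or text.lower() == "nan":
        return ()
    mods = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            name, pos_s = token.split("@")
            pos = int(pos_s)
        except ValueError as exc:
            raise SchemaError(
                f"line {line_no}: unparseable modification token {token!r}") from exc
        mods.append((pos, name, MOD_MASSES.get(name, 0.0)))
    return tuple(mods)


def read_psm_table(path) -> Cohort:
    """Read a PSM TSV/CSV into one SampleRun per distinct sample id.

    Required columns: sample, peptide, score.  Optional: mods (dialect
    ``Oxidation@4;Carbamidomethyl@2``), prev, next flanking residues.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = {"sample", "peptide", "score"} - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    runs: dict[str, SampleRun] = {}
    for idx, row in enumerate(table.itertuples(index=False), start=2):
        sample = str(row.sample)
        try:
            score = float(row.score)
        except ValueError as exc:
            raise SchemaError(f"line {idx}: bad score {row.score!r}") from exc
        mods = _parse_mods(getattr(row, "mods", ""), idx)
        prev = getattr(row, "prev", "") or None
        nxt = getattr(row, "next", "") or None
        psm = PSM(sample, str(row.peptide), score, mods, prev, nxt)
        runs.setdefault(sample, SampleRun(sample)).psms.append(psm)
    return list(runs.values())


def write_psm_table(cohort: Cohort, path) -> None:
    """Write a cohort back to the canonical TSV dialect."""
    rows = []
    for run in cohort:
        for p in run.psms:
            rows.append({
                "sample": run.sample_id,
                "peptide": p.peptide,
                "score": p.score,
                "mods": ";".join(f"{n}@{pos}" for pos, n, _ in p.modifications),
                "prev": p.prev_residue or "",
                "next": p.next_residue or "",
            })
    cols = ["sample", "peptide", "score", "mods", "prev", "next"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def mad_cutoff(scores) -> float:
    """median(scores) - median(|scores - median|), the unscaled-MAD cut-off."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("mad_cutoff needs at least one score")
    med = float(np.median(scores))
    mad = float(np.median(np.abs(scores - med)))
    return med - mad


def assign_markers(cohort: Cohort, db: MarkerDatabase,
                   max_mismatch: int = 2) -> Cohort:
    """Assign each PSM to a marker (exact match, then unique alignment) and
    type its cleavage status.

    Peptides matching no marker are classified against the templates only
    (``assigned_class``); they stay in the cohort but are excluded from
    detection matrices and cleavage statistics.
    """
    template_by_marker = {}
    for m in db.markers:
        cands = db.templates_for_class(m.reporting_class)
        tmpl = next((t for t in cands if t.length == len(m.sequence)), cands[0])
        template_by_marker[m.marker_id] = tmpl

    by_sequence = {m.sequence: m for m in db.markers}
    cache: dict[tuple, tuple[str | None, str | None, str | None]] = {}

    def resolve(p: PSM) -> tuple[str | None, str | None, str | None]:
        key = (p.peptide, p.prev_residue, p.next_residue)
        if key in cache:
            return cache[key]
        marker = by_sequence.get(p.peptide)
        if marker is None:
            # fast path: exact substring of some marker (degraded peptides)
            marker = next((m for m in db.markers if p.peptide in m.sequence), None)
        if marker is None:
            # slow path: mismatch-tolerant alignment (rare)
            marker = next((m for m in db.markers
                           if align_to_marker(p.peptide, m.sequence) is not None),
                          None)
        if marker is not None:
            status = cleavage_status(
                p.peptide, marker, template_by_marker[marker.marker_id],
                flanks=(p.prev_residue, p.next_residue))
            out = (marker.marker_id, marker.reporting_class, status)
        else:
            assigned = classify_peptide(p.peptide, db, max_mismatch=max_mismatch)
            out = (None, assigned.class_id, None)
        cache[key] = out
        return out

    result: Cohort = []
    for run in cohort:
        new_psms = []
        for p in run.psms:
            mid, cls, status = resolve(p)
            new_psms.append(replace(p, assigned_marker_id=mid,
                                    assigned_class=cls, cleavage=status))
        result.append(SampleRun(run.sample_id, new_psms,
                                run.species_truth, run.provenance))
    return result


def apply_marker_cutoffs(cohort: Cohort, db: MarkerDatabase,
                         per_sample: bool = False,
                         ) -> tuple[Cohort, pd.DataFrame]:
    """Compute per-marker MAD cut-offs and drop sub-cutoff PSMs.

    Cut-offs are computed from the pooled *eligible* PSMs of each marker
    (modifications restricted to carbamidomethylation, or none) across the
    whole cohort; ``per_sample=True`` computes them within each sample
    instead.  Markers with no eligible PSM keep all their PSMs and are
    flagged in the cut-off table.
    """
    def eligible(p: PSM) -> bool:
        return p.mod_names() <= {"Carbamidomethyl"}

    groups: dict[tuple, list[float]] = {}
    for run in cohort:
        for p in run.psms:
            if p.assigned_marker_id is None or not eligible(p):
                continue
            key = (p.assigned_marker_id, run.sample_id if per_sample else None)
            groups.setdefault(key, []).append(p.score)

    cutoffs = {key: mad_cutoff(scores) for key, scores in groups.items()}

    filtered: Cohort = []
    for run in cohort:
        kept = []
        for p in run.psms:
            key = (p.assigned_marker_id, run.sample_id if per_sample else None)
            if p.assigned_marker_id is not None and key in cutoffs \
                    and p.score < cutoffs[key]:
                continue
            kept.append(p)
        filtered.append(SampleRun(run.sample_id, kept,
                                  run.species_truth, run.provenance))

    rows = []
    for m in db.markers:
        if per_sample:
            for run in cohort:
                key = (m.marker_id, run.sample_id)
                rows.append({"marker_id": m.marker_id, "sample": run.sample_id,
                             "cutoff": cutoffs.get(key, np.nan),
                             "n_eligible": len(groups.get(key, [])),
                             "no_eligible_psm": key not in cutoffs})
        else:
            key = (m.marker_id, None)
            rows.append({"marker_id": m.marker_id,
                         "cutoff": cutoffs.get(key, np.nan),
                         "n_eligible": len(groups.get(key, [])),
                         "no_eligible_psm": key not in cutoffs})
    return filtered, pd.DataFrame(rows)


@dataclass
class DetectionMatrix:
    """Markers x samples matrix of filtered PSM counts or max scores."""

    values: pd.DataFrame  # index marker_ids, columns sample_ids
    value_kind: str       # "count" | "max_score"

    @property
    def marker_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def detected(self, sample_id: str) -> set[str]:
        col = self.values[sample_id]
        return set(col.index[col > 0])


def detection_matrix(cohort: Cohort, db: MarkerDatabase,
                     value_kind: str = "count") -> DetectionMatrix:
    """Build the markers x samples matrix over *all* database markers
    (undetected markers appear as zero rows)."""
    if value_kind not in ("count", "max_score"):
        raise ValueError(f"unknown value_kind {value_kind!r}")
    sample_ids = [run.sample_id for run in cohort]
    mat = pd.DataFrame(0.0, index=db.marker_ids(), columns=sample_ids)
    for run in cohort:
        for p in run.psms:
            if p.assigned_marker_id is None:
                continue
            if value_kind == "count":
                mat.loc[p.assigned_marker_id, run.sample_id] += 1
            else:
                cur = mat.loc[p.assigned_marker_id, run.sample_id]
                mat.loc[p.assigned_marker_id, run.sample_id] = max(cur, p.score)
    if value_kind == "count":
        mat = mat.astype(int)
    return DetectionMatrix(mat, value_kind)


def undetermined_fraction(cohort: Cohort, db: MarkerDatabase,
                          group_by: str = "overall"):
    """Percentage of marker-assigned PSMs with undetermined cleavages.

    ``group_by`` is one of ``overall`` (a float, None for an empty cohort),
    ``class`` or ``sample`` (dicts; groups with zero PSMs are omitted).
    """
    if group_by not in ("overall", "class", "sample"):
        raise ValueError(f"unknown group_by {group_by!r}")
    totals: dict[str, int] = {}
    undet: dict[str, int] = {}
    for run in cohort:
        for p in run.psms:
            if p.cleavage is None:
                continue
            if group_by == "overall":
                key = "overall"
            elif group_by == "sample":
                key = run.sample_id
            else:
                key = p.assigned_class
            totals[key] = totals.get(key, 0) + 1
            if p.cleavage == UNDETERMINED:
                undet[key] = undet.get(key, 0) + 1
    pct = {k: 100.0 * undet.get(k, 0) / n for k, n in totals.items() if n > 0}
    if group_by == "overall":
        return pct.get("overall")
    return pct
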