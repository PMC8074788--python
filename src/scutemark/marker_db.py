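"""Corneous beta-protein (CBP) marker database: data model, bundled content, I/O.

Tortoiseshell is the cornified scute layer of hard-shelled sea turtles, built
mostly from short corneous beta-proteins ("beta-keratins").  Tryptic peptides
of these proteins fall into recurrent regions named A-F: A-D cover the
conserved N-terminal/beta-sheet half, E1-E4 the glycine-rich repeats, F the
C-terminus.  Each region has a wildcard *template* (``X`` marks positions
where species-diagnostic substitutions occur) and every validated peptide
*marker* is a concrete sequence of template length, curated into one region
class and validated in one or more of the five sea-turtle species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")

#: The five sea-turtle species covered by the marker database.
CHELONIA_MYDAS = "Chelonia mydas"
CARETTA_CARETTA = "Caretta caretta"
ERETMOCHELYS_IMBRICATA = "Eretmochelys imbricata"
LEPIDOCHELYS_OLIVACEA = "Lepidochelys olivacea"
LEPIDOCHELYS_KEMPII = "Lepidochelys kempii"

SPECIES: tuple[str, ...] = (
    CHELONIA_MYDAS,
    CARETTA_CARETTA,
    ERETMOCHELYS_IMBRICATA,
    LEPIDOCHELYS_OLIVACEA,
    LEPIDOCHELYS_KEMPII,
)

#: Genus grouping; the two ridley species form the Lepidochelys genus.
DEFAULT_GENUS_MAP: dict[str, str] = {
    CHELONIA_MYDAS: "Chelonia",
    CARETTA_CARETTA: "Caretta",
    ERETMOCHELYS_IMBRICATA: "Eretmochelys",
    LEPIDOCHELYS_OLIVACEA: "Lepidochelys",
    LEPIDOCHELYS_KEMPII: "Lepidochelys",
}

#: Fixed reporting-class order, used for deterministic tie-breaking.
CLASS_ORDER: tuple[str, ...] = (
    "A", "B", "C", "D", "E1", "E2a", "E2b", "E2c", "E2d", "E3", "E4a", "E4b", "F",
)

#: Template ids; class E4a has a short (25) and a long (28 residue) form.
TEMPLATE_IDS: tuple[str, ...] = (
    "A", "B", "C", "D", "E1", "E2a", "E2b", "E2c", "E2d", "E3",
    "E4a_short", "E4a_long", "E4b", "F",
)

N_ONLY = "N_only"
C_ONLY = "C_only"
N_AND_C = "N_and_C"


class DatabaseParseError(ValueError):
    """A marker FASTA/TSV file could not be parsed."""


class DatabaseValidationError(ValueError):
    """Database content violates a structural invariant."""


def template_reporting_class(template_id: str) -> str:
    """Reporting class for a template id (both E4a forms report as "E4a")."""
    return "E4a" if template_id.startswith("E4a") else template_id


@dataclass(frozen=True)
class MarkerClassTemplate:
    """One wildcard template row: class id, template string, tryptic termini.

    ``template`` is an uppercase amino-acid string over the 20 letters plus
    ``X`` for variable positions; ``tryptic_termini`` records which peptide
    ends are expected to be genuine tryptic boundaries (the non-tryptic ends
    arise from protein termini or, for class D / E1, from the long stretch
    without K/R).  ``species_scope`` is a frozenset of species names, or the
    string "all".
    """

    class_id: str
    template: str
    tryptic_termini: str
    species_scope: frozenset[str] | str = "all"

    def __post_init__(self) -> None:
        if self.class_id not in TEMPLATE_IDS:
            raise DatabaseValidationError(f"unknown template class id {self.class_id!r}")
        bad = set(self.template) - AA_LETTERS - {"X"}
        if bad:
            raise DatabaseValidationError(
                f"template {self.class_id}: illegal characters {sorted(bad)}")
        if set(self.template) == {"X"} or not self.template:
            raise DatabaseValidationError(
                f"template {self.class_id}: needs at least one non-X residue")
        if self.tryptic_termini not in (N_ONLY, C_ONLY, N_AND_C):
            raise DatabaseValidationError(
                f"template {self.class_id}: bad termini {self.tryptic_termini!r}")

    @property
    def reporting_class(self) -> str:
        return template_reporting_class(self.class_id)

    @property
    def length(self) -> int:
        return len(self.template)

    def wildcard_positions(self) -> tuple[int, ...]:
        """1-based positions of the X wildcards."""
        return tuple(i + 1 for i, c in enumerate(self.template) if c == "X")


#: Declared residue lengths per template (checked against the strings below).
TEMPLATE_LENGTHS: dict[str, int] = {
    "A": 14, "B": 14, "C": 10, "D": 30, "E1": 19, "E2a": 28, "E2b": 16,
    "E2c": 9, "E2d": 9, "E3": 12, "E4a_short": 25, "E4a_long": 28,
    "E4b": 8, "F": 9,
}

_ALL_BUT_CM = frozenset(SPECIES) - {CHELONIA_MYDAS}

#: The fourteen template rows (region, tryptic ends, template sequence).
BUNDLED_TEMPLATES: tuple[MarkerClassTemplate, ...] = (
    MarkerClassTemplate("A", "XXSXLXYPEXGVAR", N_AND_C),
    MarkerClassTemplate("B", "PXPXXGSXNXPXVR", N_AND_C),
    MarkerClassTemplate("C", "QCPDSEVVIX", N_AND_C),
    MarkerClassTemplate("D", "PSPVVVTIPGPILSNFPQQSEVAAVGAPVV", N_ONLY),
    MarkerClassTemplate("E1", "GXGXGGSFGXGGLYGYGGR", C_ONLY),
    MarkerClassTemplate("E2a", "YGGLYGLGGLGGYGGHYGYAGLXGYGGR", N_AND_C,
                        frozenset({CHELONIA_MYDAS})),
    MarkerClassTemplate("E2b", "YGGLYGYGGXGGYGGR", C_ONLY),
    MarkerClassTemplate("E2c", "LGGFGGLXR", N_AND_C),
    MarkerClassTemplate("E2d", "XGXXXGYGR", C_ONLY),
    MarkerClassTemplate("E3", "YGXGGLXGYGGR", N_AND_C),
    MarkerClassTemplate("E4a_short", "YGGXCGYGGGYGYGGLSGSGVSXHR", C_ONLY, _ALL_BUT_CM),
    MarkerClassTemplate("E4a_long", "XGYGGLGGYXGGYGYGXGLXGSGVSXHR", C_ONLY),
    MarkerClassTemplate("E4b", "YGGXXGYR", N_AND_C),
    MarkerClassTemplate("F", "YLXGXCGPC", N_ONLY),
)


@dataclass(frozen=True)
class Marker:
    """A validated marker: curated class, concrete sequence, validated species.

    The class label is curated (alignment-based, manually checked) and is
    authoritative over template inference — some real markers do not minimise
    mismatches against their own class template.
    """

    marker_id: str
    class_id: str
    sequence: str
    species_validated: frozenset[str]
    notes: str = ""

    def __post_init__(self) -> None:
        if template_reporting_class(self.class_id) not in CLASS_ORDER:
            raise DatabaseValidationError(
                f"marker {self.marker_id}: unknown class {self.class_id!r}")
        bad = set(self.sequence) - AA_LETTERS
        if bad:
            raise DatabaseValidationError(
                f"marker {self.marker_id}: illegal residues {sorted(bad)}")

    @property
    def reporting_class(self) -> str:
        return template_reporting_class(self.class_id)


@dataclass
class MarkerDatabase:
    """Templates + markers + species bookkeeping for one marker collection."""

    templates: list[MarkerClassTemplate]
    markers: list[Marker]
    species: list[str] = field(default_factory=lambda: list(SPECIES))
    genus_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GENUS_MAP))

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -----------------------------------------------------------
    def template_by_id(self, template_id: str) -> MarkerClassTemplate:
        for t in self.templates:
            if t.class_id == template_id:
                return t
        raise KeyError(template_id)

    def templates_for_class(self, reporting_class: str) -> list[MarkerClassTemplate]:
        return [t for t in self.templates if t.reporting_class == reporting_class]

    def marker_by_id(self, marker_id: str) -> Marker:
        for m in self.markers:
            if m.marker_id == marker_id:
                return m
        raise KeyError(marker_id)

    def marker_by_sequence(self, sequence: str) -> Marker | None:
        for m in self.markers:
            if m.sequence == sequence:
                return m
        return None

    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def markers_for_species(self, species: str,
                            exclude_classes: set[str] | frozenset[str] = frozenset(),
                            ) -> set[str]:
        """Marker ids validated in ``species``, minus excluded reporting classes."""
        return {m.marker_id for m in self.markers
                if species in m.species_validated
                and m.reporting_class not in exclude_classes}

    def genera(self) -> list[str]:
        seen: list[str] = []
        for sp in self.species:
            g = self.genus_map[sp]
            if g not in seen:
                seen.append(g)
        return seen

    def species_of_genus(self, genus: str) -> set[str]:
        return {sp for sp in self.species if self.genus_map[sp] == genus}

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for tid, length in TEMPLATE_LENGTHS.items():
            try:
                t = self.template_by_id(tid)
            except KeyError:
                continue
            if t.length != length:
                raise DatabaseValidationError(
                    f"template {tid}: declared length {length} != {t.length}")
        offenders = []
        seen_ids: set[str] = set()
        known_lengths = {
            rc: {t.length for t in self.templates if t.reporting_class == rc}
            for rc in {t.reporting_class for t in self.templates}
        }
        for m in self.markers:
            if m.marker_id in seen_ids:
                offenders.append(f"{m.marker_id}: duplicate marker_id")
            seen_ids.add(m.marker_id)
            rc = m.reporting_class
            if rc not in known_lengths:
                offenders.append(f"{m.marker_id}: no template for class {rc}")
            elif len(m.sequence) not in known_lengths[rc]:
                offenders.append(
                    f"{m.marker_id}: length {len(m.sequence)} not in "
                    f"{sorted(known_lengths[rc])} for class {rc}")
            unknown_sp = m.species_validated - set(self.species)
            if unknown_sp:
                offenders.append(f"{m.marker_id}: unknown species {sorted(unknown_sp)}")
        if offenders:
            raise DatabaseValidationError("; ".join(offenders))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerDatabase):
            return NotImplemented
        return (sorted(self.templates, key=lambda t: t.class_id)
                == sorted(other.templates, key=lambda t: t.class_id)
                and sorted(self.markers, key=lambda m: m.marker_id)
                == sorted(other.markers, key=lambda m: m.marker_id)
                and self.species == other.species
                and self.genus_map == other.genus_map)


#: Markers printed in the main text; the four C/E2c/E4a ones were found in
#: every archaeological comb and are unique to E. imbricata; E1-7 was found
#: in all combs but one and validated in a single Caribbean specimen.
_PRINTED_MARKERS: tuple[Marker, ...] = (
    Marker("C-2", "C", "QAQDSEVVIR", frozenset({ERETMOCHELYS_IMBRICATA}),
           notes="P3->Q3 substitution; unique to E. imbricata"),
    Marker("C-8", "C", "QCQDSEVVIR", frozenset({ERETMOCHELYS_IMBRICATA}),
           notes="P3->Q3 substitution; unique to E. imbricata"),
    Marker("E2c-4", "E2c", "YGGLHGLGR", frozenset({ERETMOCHELYS_IMBRICATA}),
           notes="curated E2c; does not minimise mismatches vs the E2c template"),
    Marker("E4a-19.1", "E4a_long", "AGYGGLGGYLGGYGYGGGLAGSGVSAHR",
           frozenset({ERETMOCHELYS_IMBRICATA})),
    Marker("E1-7", "E1", "GPGLGGSFGPGGLYGYGGR", frozenset({ERETMOCHELYS_IMBRICATA}),
           notes="validated in the sole Caribbean specimen; E1 reliability is tentative"),
)


def bundled_database() -> MarkerDatabase:
    """The bundled database: 14 templates, 5 species, and the printed markers."""
    return MarkerDatabase(
        templates=list(BUNDLED_TEMPLATES),
        markers=list(_PRINTED_MARKERS),
    )


# -- persistence ----------------------------------------------------------

def save_database(db: MarkerDatabase, fasta_path: str | Path,
                  metadata_tsv_path: str | Path) -> None:
    """Write marker FASTA (``>marker_id|class_id``) and the metadata TSV."""
    records = [
        SeqRecord(Seq(m.sequence), id=f"{m.marker_id}|{m.class_id}", description="")
        for m in db.markers
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = []
    for m in db.markers:
        row: dict[str, object] = {
            "marker_id": m.marker_id, "class_id": m.class_id, "sequence": m.sequence,
        }
        for sp in db.species:
            row[sp] = int(sp in m.species_validated)
        row["notes"] = m.notes
        rows.append(row)
    cols = ["marker_id", "class_id", "sequence", *db.species, "notes"]
    pd.DataFrame(rows, columns=cols).to_csv(metadata_tsv_path, sep="\t", index=False)


def load_database(fasta_path: str | Path, metadata_tsv_path: str | Path,
                  ) -> MarkerDatabase:
    """Load a database from marker FASTA + metadata TSV.

    FASTA headers carry ``marker_id|class_id``; lowercase sequences are
    accepted after uppercasing (logged).  The TSV supplies curated class,
    sequence and per-species 0/1 validation flags; templates and genus map
    are the bundled ones.
    """
    fasta_seqs: dict[str, str] = {}
    fasta_class: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            if "|" not in rec.id:
                raise DatabaseParseError(
                    f"{fasta_path}: header {rec.id!r} lacks 'marker_id|class_id'")
            mid, cid = rec.id.split("|", 1)
            seq = str(rec.seq)
            if seq != seq.upper():
                logger.info("marker %s: uppercased lowercase sequence", mid)
                seq = seq.upper()
            fasta_seqs[mid] = seq
            fasta_class[mid] = cid
    except DatabaseParseError:
        raise
    except Exception as exc:  # malformed FASTA
        raise DatabaseParseError(f"{fasta_path}: {exc}") from exc

    table = _read_marker_tsv(metadata_tsv_path)
    markers = []
    for _, row in table.iterrows():
        mid = str(row["marker_id"])
        seq = str(row["sequence"]).upper()
        if mid in fasta_seqs and fasta_seqs[mid] != seq:
            raise DatabaseValidationError(
                f"{mid}: FASTA sequence differs from TSV sequence")
        validated = frozenset(sp for sp in SPECIES if sp in table.columns and row[sp])
        notes = str(row["notes"]) if "notes" in table.columns else ""
        markers.append(Marker(mid, str(row["class_id"]), seq, validated, notes))
    return MarkerDatabase(templates=list(BUNDLED_TEMPLATES), markers=markers)


def _read_marker_tsv(path: str | Path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except Exception as exc:
        raise DatabaseParseError(f"{path}: {exc}") from exc
    required = {"marker_id", "class_id", "sequence"}
    missing = required - set(table.columns)
    if missing:
        raise DatabaseParseError(f"{path}: missing columns {sorted(missing)}")
    for sp in SPECIES:
        if sp in table.columns:
            table[sp] = table[sp].astype(str).str.strip().map(
                lambda v: v not in ("0", "", "0.0"))
    bad = [cid for cid in table["class_id"]
           if template_reporting_class(cid) not in CLASS_ORDER or
           (cid not in TEMPLATE_IDS and cid not in CLASS_ORDER)]
    if bad:
        raise DatabaseValidationError(f"{path}: unknown class ids {sorted(set(bad))}")
    return table


def import_supplementary_markers(tsv_path: str | Path, db: MarkerDatabase,
                                 ) -> MarkerDatabase:
    """Merge a supplementary marker TSV into ``db`` (incoming rows win).

    The TSV uses the metadata dialect (marker_id, class_id, sequence, one 0/1
    column per species).  Duplicate marker_ids are resolved in favour of the
    incoming rows, with a log entry per replacement.
    """
    table = _read_marker_tsv(tsv_path)
    incoming: dict[str, Marker] = {}
    for _, row in table.iterrows():
        mid = str(row["marker_id"])
        validated = frozenset(sp for sp in SPECIES if sp in table.columns and row[sp])
        notes = str(row["notes"]) if "notes" in table.columns else ""
        incoming[mid] = Marker(mid, str(row["class_id"]),
                               str(row["sequence"]).upper(), validated, notes)
    merged: list[Marker] = []
    for m in db.markers:
        if m.marker_id in incoming:
            new = incoming.pop(m.marker_id)
            if replace(new, notes="") != replace(m, notes=""):
                logger.info("marker %s replaced by supplementary row", m.marker_id)
            merged.append(new)
        else:
            merged.append(m)
    merged.extend(incoming.values())
    return MarkerDatabase(templates=list(db.templates), markers=merged,
                          species=list(db.species), genus_map=dict(db.genus_map))
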