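"""Seeded generator of synthetic PSM tables for modern and degraded samples.

The generator emulates the observable structure of scute proteomics data:
per-species marker repertoires, -10lgP score distributions, PSM counts,
site-level oxidation/dioxidation and phospho-serine events, and hydrolytic
degradation — class-biased marker dropout (the glycine-rich E4 termini and
the A terminus degrade fastest), inflated non-tryptic "undetermined"
cleavages realised by trimming peptide termini, and rapid loss of the
alpha-keratin background.  Every stochastic choice flows from one integer
seed; a truth sidecar records the generating parameters and per-PSM truth
for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .marker_db import (
    CHELONIA_MYDAS,
    C_ONLY,
    N_AND_C,
    N_ONLY,
    MarkerDatabase,
)
from .peptide_tools import TERMINUS
from .psm_model import PSM, Cohort, SampleRun

#: Class-wise degradation multipliers: detection probability is
#: base_detect_p * (1 - d * weight).  E4 and A lose markers fastest.
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "A": 0.8, "B": 0.5, "C": 0.4, "D": 0.4, "E1": 0.5, "E2a": 0.5,
    "E2b": 0.5, "E2c": 0.5, "E2d": 0.5, "E3": 0.5, "E4a": 1.0, "E4b": 1.0,
    "F": 0.4,
}

#: Non-marker tryptic peptides standing in for the alpha-keratin background.
#: Lengths deliberately avoid every template length, so they classify to no
#: CBP class.  Synthetic sequences, no biological meaning.
ALPHA_KERATIN_DECOYS: tuple[str, ...] = (
    "SLNNQFASFIDKVR",          # 15
    "QSLEASLAETEGR",           # 13
    "AETECQNTEYQQLLDIK",       # 17
    "VTMQNLNDFLASYLDKVR",      # 18
    "ISSVLAGGSCLAPNTYSGGLR",   # 21
    "NLDLDSIIAEVKAQYEEIAR",    # 20
    "DVEEWYIQTLK",             # 11
    "TAAENEFVTLK",             # 11
    "QNLEPLFEQYINNLR",         # 15
)


def _decoy_pool() -> list[str]:
    """Decoys whose lengths differ from every marker-template length."""
    template_lengths = {8, 9, 10, 12, 14, 16, 19, 25, 28, 30}
    return [s for s in ALPHA_KERATIN_DECOYS if len(s) not in template_lengths]


@dataclass
class GeneratorConfig:
    """Study conditions for one batch of synthetic specimens of a species.

    Defaults emulate a well-preserved modern reference specimen; degradation
    ``d`` in [0, 1] moves the sample toward the archaeological regime.
    """

    species: str
    n_specimens: int = 5
    d: float = 0.0
    base_detect_p: float = 0.85
    class_degradation_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))
    score_mean: float = 45.0
    score_sd: float = 8.0
    score_floor: float = 25.0
    psm_count_mean: float = 4.0
    u0: float = 0.30          # undetermined-cleavage probability at d=0
    u_slope: float = 0.30     # u(d) = u0 + u_slope * d
    p_ox: float = 0.05        # per-site oxidation probability
    p_diox: float | None = None           # default p_ox / 2
    p_phospho_SAHR: float = 0.5
    p_phospho_SCHR: float = 0.0
    alpha_keratin_background: float = 30.0  # expected decoy PSMs at d=0
    sample_prefix: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_diox is None:
            self.p_diox = self.p_ox / 2.0
        if not 0.0 <= self.d <= 1.0:
            raise ValueError(f"degradation d={self.d} outside [0, 1]")
        for name in ("base_detect_p", "u0", "u_slope", "p_ox", "p_diox",
                     "p_phospho_SAHR", "p_phospho_SCHR"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_ox + self.p_diox > 1.0:
            raise ValueError("p_ox + p_diox exceeds 1")

    @property
    def undetermined_probability(self) -> float:
        return self.u0 + self.u_slope * self.d

    def echo(self) -> dict:
        return asdict(self)


def default_config_for_species(species: str, **overrides) -> GeneratorConfig:
    """Species defaults: C. mydas runs at twice the oxidative site rates."""
    cfg = GeneratorConfig(species=species, **overrides)
    if species == CHELONIA_MYDAS and "p_ox" not in overrides:
        cfg.p_ox = 2 * 0.05
        cfg.p_diox = cfg.p_ox / 2.0
    return cfg


@dataclass
class TruthRecord:
    """Ground truth for one synthetic specimen, row-aligned with its PSMs."""

    sample_id: str
    species: str
    d: float
    marker_detected: dict[str, bool]
    psm_marker: list[str | None]
    psm_undetermined: list[bool]
    n_ox_sites: int
    n_diox_sites: int
    n_potential_sites: int       # sites in emitted peptides (marker PSMs)
    n_phospho_SAHR: int
    n_phospho_SCHR: int
    config: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _flanks_for_full_marker(termini: str) -> tuple[str, str]:
    """Plausible flanking residues for a peptide spanning its whole marker."""
    prev = "R" if termini in (N_ONLY, N_AND_C) else "G"
    nxt = "G" if termini in (C_ONLY, N_AND_C) else TERMINUS
    return prev, nxt


def generate_specimen(config: GeneratorConfig, db: MarkerDatabase,
                      sample_id: str, rng: np.random.Generator | None = None,
                      ) -> tuple[SampleRun, TruthRecord]:
    """Draw one synthetic specimen of ``config.species``.

    Per validated marker: Bernoulli detection at base_detect_p * (1 - d *
    class weight); a detected marker yields a zero-truncated Poisson number
    of PSMs with truncated-normal scores (mean depressed by 5d, floored at
    the search-engine score threshold).  Each PSM is independently realised
    with undetermined cleavages (both termini trimmed into the marker) with
    probability u0 + u_slope*d; oxidisable sites and context-dependent
    phospho-serines receive Bernoulli modification draws.  Alpha-keratin
    background PSMs shrink proportionally to (1 - d).
    """
    if config.species not in db.species:
        raise ValueError(f"species {config.species!r} not in database")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    termini_by_class = {t.reporting_class: t.tryptic_termini for t in db.templates}
    weights = config.class_degradation_weights
    u = config.undetermined_probability
    score_loc = config.score_mean - 5.0 * config.d

    marker_detected: dict[str, bool] = {}
    peptides: list[tuple[str, str | None, str, str, bool]] = []
    n_ox = n_diox = n_pot = n_ph_sahr = n_ph_schr = 0
    mods_per_psm: list[list[tuple[int, str, float]]] = []
    truth_marker: list[str | None] = []
    truth_undet: list[bool] = []

    from .peptide_tools import MOD_MASSES
    from .ptm_stats import OXIDIZABLE

    for m in db.markers:
        if config.species not in m.species_validated:
            continue
        w = weights.get(m.reporting_class, 0.5)
        p_det = config.base_detect_p * max(0.0, 1.0 - config.d * w)
        det = bool(rng.random() < p_det)
        marker_detected[m.marker_id] = det
        if not det:
            continue
        n_psm = max(1, int(rng.poisson(config.psm_count_mean)))
        seq = m.sequence
        L = len(seq)
        for _ in range(n_psm):
            undet = bool(rng.random() < u) and L >= 8
            if undet:
                a = int(rng.integers(1, min(3, L - 7) + 1))
                b = int(rng.integers(1, min(3, L - 6 - a) + 1))
                pep = seq[a:L - b]
                prev, nxt = seq[a - 1], seq[L - b]
            else:
                pep = seq
                prev, nxt = _flanks_for_full_marker(
                    termini_by_class[m.reporting_class])
            mods: list[tuple[int, str, float]] = []
            for i, res in enumerate(pep, start=1):
                if res == "C":
                    mods.append((i, "Carbamidomethyl",
                                 MOD_MASSES["Carbamidomethyl"]))
                if res in OXIDIZABLE:
                    n_pot += 1
                    r = rng.random()
                    if r < config.p_ox:
                        mods.append((i, "Oxidation", MOD_MASSES["Oxidation"]))
                        n_ox += 1
                    elif r < config.p_ox + config.p_diox:
                        mods.append((i, "Dioxidation", MOD_MASSES["Dioxidation"]))
                        n_diox += 1
                if res == "S":
                    window = pep[i - 1:i + 3]
                    if window == "SAHR":
                        if rng.random() < config.p_phospho_SAHR:
                            mods.append((i, "Phospho", MOD_MASSES["Phospho"]))
                            n_ph_sahr += 1
                    elif window == "SCHR":
                        if rng.random() < config.p_phospho_SCHR:
                            mods.append((i, "Phospho", MOD_MASSES["Phospho"]))
                            n_ph_schr += 1
            peptides.append((pep, m.marker_id, prev, nxt, undet))
            mods_per_psm.append(mods)
            truth_marker.append(m.marker_id)
            truth_undet.append(undet)

    n_bg = int(rng.poisson(config.alpha_keratin_background * (1.0 - config.d)))
    pool = _decoy_pool()
    for _ in range(n_bg):
        pep = pool[int(rng.integers(0, len(pool)))]
        peptides.append((pep, None, "K", "G", False))
        mods_per_psm.append([(i, "Carbamidomethyl", MOD_MASSES["Carbamidomethyl"])
                             for i, r in enumerate(pep, start=1) if r == "C"])
        truth_marker.append(None)
        truth_undet.append(False)

    n_total = len(peptides)
    a_trunc = (config.score_floor - score_loc) / config.score_sd
    scores = truncnorm.rvs(a_trunc, np.inf, loc=score_loc, scale=config.score_sd,
                           size=n_total, random_state=rng)

    psms = [
        PSM(sample_id, pep, float(score), tuple(mods), prev, nxt)
        for (pep, _, prev, nxt, _), mods, score
        in zip(peptides, mods_per_psm, scores)
    ]
    run = SampleRun(sample_id, psms, species_truth=config.species,
                    provenance=f"synthetic d={config.d}")
    truth = TruthRecord(sample_id, config.species, config.d, marker_detected,
                        truth_marker, truth_undet, n_ox, n_diox, n_pot,
                        n_ph_sahr, n_ph_schr, config.echo())
    return run, truth


def generate_cohort(configs: list[GeneratorConfig], db: MarkerDatabase,
                    ) -> tuple[Cohort, dict[str, TruthRecord]]:
    """Generate all specimens of all configs; sample ids must be unique."""
    if not configs:
        raise ValueError("need at least one GeneratorConfig")
    cohort: Cohort = []
    truths: dict[str, TruthRecord] = {}
    for cfg in configs:
        rng = np.random.default_rng(cfg.seed)
        prefix = cfg.sample_prefix or cfg.species.split()[-1][:4].upper()
        for i in range(cfg.n_specimens):
            sid = f"{prefix}-{i + 1}"
            if sid in truths:
                raise ValueError(f"duplicate sample_id {sid!r}")
            run, truth = generate_specimen(cfg, db, sid, rng=rng)
            cohort.append(run)
            truths[sid] = truth
    return cohort, truths


def modern_reference_configs(db: MarkerDatabase, seed: int = 0,
                             species: list[str] | None = None,
                             n_specimens: dict[str, int] | None = None,
                             **overrides) -> list[GeneratorConfig]:
    """Configs emulating the modern reference panel (one config per species).

    Specimen counts default to the reference panel sizes: 4 C. mydas,
    5 C. caretta, 5 E. imbricata, 3 L. olivacea, 1 L. kempii.
    """
    default_n = {"Chelonia mydas": 4, "Caretta caretta": 5,
                 "Eretmochelys imbricata": 5, "Lepidochelys olivacea": 3,
                 "Lepidochelys kempii": 1}
    species = species or list(db.species)
    n_specimens = n_specimens or default_n
    return [
        default_config_for_species(
            sp, n_specimens=n_specimens.get(sp, 5), seed=seed + j, **overrides)
        for j, sp in enumerate(species)
    ]
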