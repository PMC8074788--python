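# Methods

This note documents the models and procedures implemented in `scutemark`,
the parameter choices that matter, what the synthetic data generator does
and does not emulate, and the design decisions taken where the workflow is
genuinely open.

## Marker database

The database couples fourteen wildcard **templates** — one per CBP peptide
class (A, B, C, D, E1, E2a–d, E3, E4a short/long, E4b, F) — with concrete
validated **markers**.  A template is a fixed-length amino-acid string in
which `X` marks positions where species-diagnostic substitutions occur;
each template also records which peptide termini are genuine tryptic
boundaries (both, N only, or C only: the glycine-rich region lacks K/R over
long stretches, so several classes have only one reliable tryptic end).
Class E4a has a 25-residue and a 28-residue form under one reporting class;
the short form does not occur in *C. mydas*.  Markers carry a curated class
label that is authoritative over template inference: real markers exist
(e.g. E2c-4, YGGLHGLGR) that do not minimise mismatches against their own
class template, because curation used alignments over full protein models,
not template distance.  Template inference (`classify_peptide`) is for
unlabelled peptides only.

Species are fixed binomial strings; genus grouping is a database-level map
(the two ridleys form *Lepidochelys*), never hard-coded in analysis code.

### Full-scale synthetic marker table

The complete validated marker list is not redistributable, so
`synthetic_s1.py` constructs a deterministic stand-in of 187 markers whose
species-validation patterns reproduce every published summary count exactly
(class totals A=34, B=53, E4a=47; 33 markers in all five species; 56 in all
four genera; species-unique counts 20/19/17/15/2; 21 markers exclusively
shared by *E. imbricata* + *C. caretta* + *Lepidochelys*; 124 markers in
*E. imbricata*).  It contains no class-D markers: class D was reported
"data not shown" and is excluded from species differentiation, and the
published 124-marker *E. imbricata* total is only consistent with a D-free
table.  Wildcards are filled from a fixed residue rotation that never
places K/R at internal positions (markers must remain clean tryptic
peptides); narrative per-species class counts from the discussion (e.g.
E4a: 21/22/27) are only approximated.  Set-algebra results on this table
test the machinery at realistic scale; they do not add evidence about the
real marker list beyond the published totals built into its construction.

## Score filtering

Per marker, the cut-off is `median(scores) − MAD(scores)` with the
**unscaled** MAD (no 1.4826 normal-consistency factor), computed from the
pooled PSMs whose modifications are restricted to carbamidomethylation,
across all samples of the cohort; PSMs of that marker scoring below the
cut-off are removed.  Markers with no eligible PSM keep all PSMs and are
flagged.  A per-sample cut-off mode exists behind a flag; pooling is the
default because validation treats each marker sequence, not each specimen,
as the unit.  Filtering is monotone: raising a cut-off can only empty
detection-matrix cells.

## Cleavage typing and the degradation proxy

A PSM is aligned to its marker (exact substring first, then a single-offset
scan allowing ≤2 substitutions; multiple equally good offsets count as no
alignment).  Each terminus is *determined* if it coincides with the marker
boundary on a side the template marks as tryptic, if the flanking residue
shows a true tryptic junction (preceded by K/R; peptide itself ending in
K/R), or if it sits at a protein terminus.  Both ends determined →
`determined`; one → `semi`; neither, or no unique alignment →
`undetermined`.  The percentage of marker-assigned PSMs with undetermined
cleavages is the hydrolysis proxy: ≈30 % in fresh scute material and
rising steeply with degradation.  PSMs that match no marker (background
proteins) are excluded from the denominator.

## PTM site occupancy

Potential oxidation sites are the P, Y, H, W residues of a marker; the
denominator is sites × PSM count per (marker, sample), the numerator counts
site-level observations of +15.99 (oxidation) and +31.99 (dioxidation) on
those residues — a PSM with two oxidised residues contributes two.  A
PSM-level mode (at most one count per PSM) is available behind a flag.
Oxidation on other residues (e.g. methionine) is excluded from both sides
and logged.  Phospho-serine events are bucketed by the following residue
and by the diagnostic C-terminal contexts SAHR (frequently phosphorylated)
versus SCHR (never observed phosphorylated).

## Species assignment

For each species the match fraction is
`100 · |detections ∩ repertoire| / |repertoire|`, with class D removed from
both sides by default (class E1 removable by flag: its tryptic context
makes it unreliable, though one printed E1 marker is retained by default).
The final call is **anchored in unique markers**: among species with at
least one detected unique marker, the one with the maximal fraction is
called; no unique support anywhere, or a tie among supported species,
yields `inconclusive`.  Raw fraction ranking alone is deliberately not
trusted: a species whose repertoire nests almost entirely inside another's
(here *L. kempii* inside *E. imbricata*) can out-rank it on fractions under
class-biased marker loss without a single discriminating marker — the
nesting artifact, not evidence.  This rule is the package's documented
resolution of a decision that marker-based identification practice leaves
informal.
*L. kempii*, represented by one reference specimen and two unique markers
(both in the fast-degrading E4b class), is not reliably callable at high
degradation; recovery simulations therefore use the archaeologically
relevant *E. imbricata* scenario.

## Multivariate classification

Features are the highest retained −10lgP score per marker (0 when
undetected), one feature per marker id.  PCA is centred and unscaled
(prcomp-style SVD; scores × loadingsᵀ + mean reconstructs the matrix).  The
SOM is a 4 × 4 square grid trained online for 10 000 presentations on the
centred feature matrix (not on PCA scores; a flag could change this, PCA
serves visualisation): per iteration one random sample updates its
best-matching unit and Gaussian neighbourhood, learning rate decaying
linearly 0.05 → 0.01 and radius from half the grid diagonal to 1 — common
Kohonen defaults.  Node clusters come from k-means over the codebooks with
k chosen by the elbow as the maximal second difference of **log** WCSS;
the raw-second-difference form systematically picks k = 2 on geometrically
decaying curves, whereas the scale-free form recovers obvious fixtures and
the four genus clusters alike.  Query samples are assigned BMU → node
cluster and never influence training; missing marker columns are
zero-filled with a warning, unknown columns are an error, all-zero feature
vectors are flagged low-information.

## Synthetic data generator

The generator emulates, per specimen of a given species: Bernoulli marker
detection at `base_detect_p · (1 − d·w_class)` with d ∈ [0,1] the
degradation level and class weights w (E4a/E4b 1.0, A 0.8, others 0.4–0.5)
shaping the class-biased loss seen in degraded material (E4 classes lose
the largest marker fraction, then A); a zero-truncated Poisson PSM count
per detected marker (detection implies at least one PSM, so the Poisson
draw is floored at 1); −10lgP scores from a normal (mean 45 − 5d, sd 8)
truncated at the search-engine floor of 25 — the −5d mean depression is an
invented nuisance parameter to exercise the MAD filter; undetermined
cleavages with probability `u0 + u_slope·d` (defaults 0.30 + 0.30·d,
matching the ≈30 % fresh-material baseline and its near-doubling in
archaeological samples), realised by trimming 1–3 residues from both
termini; per-site oxidation/dioxidation Bernoulli draws on P/Y/H/W
(defaults 0.05 and 0.025; doubled for *C. mydas*, whose scutes show about
twice the oxidative modification of the other genera); phospho-serine
draws by context (SAHR 0.5, SCHR exactly 0); and an α-keratin background of
non-CBP tryptic decoy peptides with expected count ∝ (1 − d), reflecting
the rapid loss of α-keratins in ancient samples.  Decoy lengths
deliberately avoid every template length so they classify to no CBP class.

What it does **not** emulate: spectrum-level effects (no m/z peaks, no
chimeric spectra), chemical kinetics of hydrolysis, deamidation (negligible
in this material), inter-specimen repertoire variability beyond Bernoulli
detection, and correlated marker dropout within a protein.  Passing
recovery tests therefore demonstrates that the estimators are faithful to
this generative model, not that real archaeological data meet its
assumptions.

Every draw flows from one integer seed; identical config + seed gives a
byte-identical PSM table and truth sidecar.

## Problem sizes used in tests

Unit and property tests run on small cohorts (1–10 specimens, a few hundred
to a few thousand PSMs); the recovery checks use 100 single-specimen
replicates at d = 0.5, 20 seeds of 4-genus references (20 samples each) for
the SOM/ARI check, and ≥10 000 potential sites for the oxidation binomial
check — sizes at which the binomial/ARI tolerances are informative while
the whole suite runs in well under a minute.  The oxidation-recovery
configuration sets u0 = 0 so the site-occupancy estimator is isolated from
terminus trimming: the published denominator convention (full-marker sites
× PSM count) would otherwise introduce a small deterministic undercount
unrelated to the statistic under test.

## Known limitations

* The synthetic marker table reproduces published totals, not real
  sequences; analyses that depend on the actual residue content of the
  supplementary markers cannot be validated here.
* Cleavage typing depends on flanking-residue columns when peptides do not
  reach marker boundaries; PSM tables without flanks bias `semi` calls
  toward `undetermined` for classes with one non-tryptic terminus.
* The MAD cut-off assumes enough eligible PSMs per marker for a stable
  median; singleton markers pass through unfiltered (flagged).
* Genus-level results treat *Lepidochelys* as one unit; the single
  *L. kempii* reference specimen limits species-level claims within the
  genus.
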