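# scutemark

Peptide-marker identification of sea-turtle tortoiseshell from corneous
beta-protein (CBP) proteomics.

Tortoiseshell — the cornified scute layer of hard-shelled marine turtles —
was a prized raw material for centuries and is still a driver of illegal
poaching, above all of the hawksbill turtle *Eretmochelys imbricata*.
Because the scutes are built almost entirely from short corneous
beta-proteins ("β-keratins"), tryptic peptides of these proteins carry
species-diagnostic substitutions.  `scutemark` implements the full
marker-based identification workflow for conservators, archaeometrists and
wildlife-forensics labs working from bottom-up LC-MS/MS peptide-spectrum
matches (PSMs):

* a **marker database** of the five sea-turtle species
  (*Chelonia mydas*, *Caretta caretta*, *E. imbricata*,
  *Lepidochelys olivacea*, *L. kempii*): fourteen wildcard templates for the
  CBP peptide classes A–F (`X` marks variable residues) plus validated
  marker sequences with per-species flags, read and written as FASTA + TSV;
* **peptide tools**: wildcard template matching with I/L equivalence,
  minimum-mismatch class assignment, in-silico (semi)specific tryptic
  digestion, cleavage-status typing and monoisotopic masses;
* **PSM filtering**: per-marker score cut-offs equal to
  `median(score) − MAD(score)` (unscaled median absolute deviation) over the
  pooled carbamidomethyl-only/unmodified PSMs, then markers × samples
  detection matrices;
* **species assignment** from marker-set algebra: per-species match
  fractions `100·|detected ∩ repertoire| / |repertoire|`, anchored in
  markers *unique* to one species;
* **degradation and PTM statistics**: percentage of PSMs with undetermined
  cleavages (a hydrolysis proxy), class-wise marker loss, site-occupancy of
  oxidation/dioxidation on P/Y/H/W, and phospho-serine SAHR/SCHR motifs;
* **multivariate classification**: centred, unscaled PCA of
  highest-score-per-marker features, a 4 × 4 Kohonen self-organizing map
  (10 000 training presentations), elbow *k*-means over the SOM codebooks,
  and projection of unknown (e.g. archaeological) samples onto the modern
  reference system;
* a **seeded synthetic PSM generator** that emulates modern reference
  specimens and degraded archaeological samples, with a ground-truth sidecar
  for parameter-recovery testing.

Because the full validated marker list is not available for
redistribution, the package ships a *synthetic* full-scale stand-in (`scutemark.synthetic_s1`) that reproduces every published summary
count (187 markers; 124 in *E. imbricata*; 20 unique to it; …) while its
individual sequences are deterministic template fills with no biological
meaning.  The five markers printed in the main text (C-2, C-8, E2c-4,
E4a-19.1, E1-7) are bundled verbatim.

## Worked example

Simulate one heavily degraded "comb" (degradation d = 0.7) and identify it:

```sh
cat > combs.yaml <<'EOF'
- {species: Eretmochelys imbricata, n_specimens: 1, d: 0.7,
   sample_prefix: COMB, seed: 42}
EOF
scutemark simulate --config combs.yaml --out sim
scutemark identify --psm sim/psms.tsv --out report
```

prints `COMB-1: Eretmochelys imbricata`, and
`report/species_call_COMB-1.json` contains:

```
call: Eretmochelys imbricata
fractions: {Caretta caretta: 43.0, Chelonia mydas: 38.9,
            Eretmochelys imbricata: 54.0, Lepidochelys kempii: 50.8,
            Lepidochelys olivacea: 41.2}
unique hit: [B-23, B-24, C-2, C-8, E2c-4, E4a-14, ...]
undetermined overall: 48.4
```

Reading: the sample detects 54.0 % of the hawksbill repertoire — in the
range reported for poorly preserved archaeological combs (52–56 %) — and,
decisively, several markers unique to *E. imbricata*, including the four
(C-2, C-8, E2c-4, E4a-19.1) found in every real comb.  Note that the raw
fraction of *L. kempii* (50.8 %) is nearly as high purely because its small
repertoire nests inside the hawksbill's; the call is therefore anchored in
unique-marker evidence, not fractions alone.  The undetermined-cleavage
percentage (48.4 %) is far above the ≈30 % baseline of fresh scute
material, flagging heavy hydrolytic degradation.

Classify samples against a modern reference panel (PCA + SOM + elbow
*k*-means; four genus clusters):

```sh
scutemark classify --reference refs.tsv --query sim/psms.tsv \
    --grid 4x4 --iterations 10000 --seed 0 --out cls
```

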