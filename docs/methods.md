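# Methods

## The energy model

PSEE treats a residue's local sequence neighborhood as a proxy for its
contact environment in the folded state. For residue *i*, the 2·CR
neighbors within the contact radius CR contribute their pairwise contact
potential P(aa_i, aa_j), each weighted by the partner's proportional burial
pBur(j); the sum is normalized by the constant 2·CR and finally weighted by
the target's own burial pBur(i). The model's assumptions are that
(1) sequence-local residues are plausible contact partners, (2) a residue's
predicted burial measures how much contact surface it actually offers, and
(3) the statistical contact potential — derived elsewhere from globular
protein structures — transfers to this sequence-local setting. Negative
(favorable) energies then accumulate for buried residues surrounded by
burial-weighted attractive partners, which is exactly the regime of ordered
cores; disordered regions, being hydrophilic and exposed, score near zero
or positive.

Proportional exposure is pExp = predicted ASA / reference ASA, with the
Gly-X-Gly extended-tripeptide reference areas (packaged, Å²); burial is its
complement. ASA predictors are unconstrained regressors, so pExp is clipped
into [0, 1] by default (`clip_exposure`) to keep burial a proportion.

## Packaged tables

* `contact_energies.tsv` — the 20×20 contact potential, row = target.
  The printed source is asymmetric in a dozen cells (the P row partially
  duplicates the Q row, suggesting a transcription artifact in the source);
  the table is shipped exactly as printed, the default lookup is row-major
  with the target first, and symmetrization (averaging the two orders) is
  an explicit opt-in. `matrix_asymmetry_report` enumerates all asymmetric
  pairs so users can audit the effect.
* `asa_reference.tsv` — Gly-X-Gly reference areas, Å².
* `hydrophobicity.tsv` — the Eisenberg consensus hydrophobicity scale plus
  the conventional 10/10 hydrophobic/hydrophilic split of the alphabet.
  The scale is one standard choice among several; tests constrain only
  sign and ordering properties, never exact values.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| contact radius CR | 9 | neighbors per side; 2·CR partners total |
| clip_exposure | on | truncate pExp into [0, 1] |
| normalize_by_count | off | divide by the actual partner count at termini |
| window w | 21 | sliding-window width for classifier features |
| per-residue features F | 57 | full schema; w·F = 1197 per residue |
| SVM cost C | 0.5 | misclassification cost |
| SVM γ | 0.0078125 (2⁻⁷) | RBF kernel width |
| decision threshold | 0.79 | raw disorder probability cut; rescaled to 0.5 |

CR = 9 is the radius that best separates ordered from disordered residues
in the reference analysis; `sweep_contact_radius` re-derives the choice on
any labeled dataset (argmax of MCC, smallest CR on ties — the cheaper
model). C and γ are the grid-search optimum of the reference predictor and
are taken as given; the package accepts user overrides but does not search.

## Numerical and edge-case conventions

* **Termini.** The divisor of the energy sum stays 2·CR even where fewer
  partners exist, because the defining formula normalizes unconditionally;
  this shrinks |PSEE| toward zero at chain ends. `normalize_by_count`
  offers the per-count alternative, and a test asserts the fixed-divisor
  magnitude never exceeds the per-count one.
* **Non-standard residues** (X, B, Z, U): the affected position's PSEE is
  marked unavailable (`None`, never zero), the position is excluded both as
  a target and as a partner, and a warning is logged. A strict mode rejects
  the sequence outright, mirroring pipelines that drop whole chains.
* **Cysteine.** The C–C potential (−39.58) dwarfs every other entry, so
  cysteine-rich neighborhoods can produce outlying energies; any |PSEE|
  above 10 triggers a diagnostic log line but is computed normally —
  exclusion is the caller's decision.
* **Threshold ties.** A residue with PSEE exactly at t(PSEE) is assigned to
  the ordered (favorable) class, deterministically.
* **IDR length strata** are ≤5, 6–20, 21–40, ≥41 residues (closing the
  boundary overlap at 40 that an open/closed interval mix would create).
* **Midpoint threshold** is computed from unrounded class means.
* **Youden threshold.** Candidates are 0, 1 and the midpoints between
  consecutive distinct scores; "score ≥ threshold" is called disordered;
  ties break toward higher specificity, then the lower threshold.
* **Probability rescaling** maps [0, θ) linearly onto [0, 0.5) and [θ, 1]
  onto [0.5, 1]; it is continuous, strictly monotone, and exactly invertible.
* **MCC** returns 0 when a denominator factor vanishes (logged); balanced
  accuracy and precision raise instead, naming the empty margin, because a
  silent default there would hide a degenerate evaluation.
* **Precision–recall sweep** stops at the first threshold reaching full
  recall; beyond it precision only degrades with no recall gain.
* **Coordinates** are 1-based inclusive everywhere user-facing.

## Classifier

Feature vectors are the concatenated per-residue blocks of a 21-residue
window (zero-padded past the termini — the terminal-indicator feature
already encodes end proximity, so padding carries no extra signal).
Interior residues get terminal indicator 0; the first five positions get
−1.0…−0.2 and the last five +0.2…+1.0 in 0.2 steps, with the N-terminal
rule winning for the first ⌈L/2⌉ positions of chains shorter than ten
residues. The classifier is an RBF-kernel SVM; features are first scaled
per column into [−1, 1] (the conventional LIBSVM preprocessing, which keeps
squared distances on the scale the default γ expects), and probabilities
come from sigmoid calibration fitted via an internal stratified 5-fold
cross-validation whose fold assignment derives from the caller's seed —
training is bit-reproducible for a fixed seed. The full 57-column schema is
a named layout; the columns a production pipeline sources from external
tools (PSSM, secondary-structure probabilities, torsion fluctuations,
monogram/bigram, physicochemical properties) are accepted from user files
and are filled by the synthetic generator in tests.

## Ranking

Predictors are ranked per metric (ACC, PPV, MCC, AUC) with competition
ranking — tied values share the best rank, the next rank is skipped
(1, 2, 2, 4) — ties detected by exact equality of the values as given.
The cumulative score S_c sums the four ranks, and the final standing is
competition ranking on ascending S_c. The test suite validates this
machinery against four published 8-predictor comparison tables. One of the
four reproduces in full; the others are internally inconsistent as
published (final ranks following dense rather than competition ranking in
one, per-metric ranks evidently computed on unrounded values in the
other two, including one row whose printed values duplicate a neighbor's
while its ranks do not), so the corresponding acceptance checks document
the discrepancy rather than reproduce it. The unit suite asserts exactly
the self-consistent parts.

## Synthetic data

The generator emulates the one contrast the energy model rests on: ordered
segments are hydrophobic-biased (3:1 sampling odds) and buried (relative
exposure ~ Beta with mean 0.25), disordered segments hydrophilic-biased and
exposed (mean 0.67); the two means straddle the conventional 25% burial
cut. Sequences alternate ordered/disordered segments of 5–40 residues;
ASA is sampled exposure × reference area, so the exposure normalization
recovers the sampled value exactly (a designed round-trip). Defaults are
24 sequences of 60–160 residues at seed 7; the classifier tests use a
10-sequence variant of the same spec so the six SVM fits of the ablation
experiment stay fast. Synthetic feature tables carry genuinely computed
PSEE and terminal-indicator columns; all other columns are unit-variance
Gaussian noise with a ±0.25 class shift — weak per-feature signal, as
individual real features are weak predictors.

What passing synthetic tests do show: the energy layer, thresholding,
sweeping, windowing, training and evaluation plumbing behave correctly on
data with the assumed composition/exposure structure, and the PSEE feature
carries real signal the classifier can exploit. What they do not show:
performance on real proteins, where exposure predictions are noisy and
correlated, composition biases are weaker, disorder is diverse (molten
globules, conditionally folded binders), and the external feature columns
are informative rather than noise.

## Known limitations

* The contact potential is used as printed, including its asymmetric
  cells; whether the original analysis symmetrized it is unknowable from
  the source, so the default is faithful row-major lookup.
* Partners with unavailable burial are skipped (treated as contributing
  zero), one of several defensible conventions.
* The reference dataset-level numbers (mean energies near −0.5/−0.14 per
  class, region means −1.00/−0.391, hydrophobicity correlation −0.86)
  depend on curated disorder databases plus external ASA predictions and
  are not recomputable from the package alone; the synthetic analogues
  reproduce their qualitative structure (sign, ordering, separation), not
  their values.
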