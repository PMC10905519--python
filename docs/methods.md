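# Methods note

This note records the modelling choices, parameter defaults, numerical
conventions and known limitations of the package. It makes no empirical
claims beyond what the test suite and `scripts/acceptance.py` compute.

## Coordinates and sequence conventions

All intervals are 0-based, half-open internally; GFF3 (1-based closed)
and BED (0-based half-open) are converted at the I/O boundary. The
transcription start site of a gene on the plus strand is its `start`
coordinate; on the minus strand it is `end − 1`. The promoter of length
`L` is `[tss − L, tss)` on the plus strand and, symmetrically in
transcription orientation, `[tss + 1, tss + 1 + L)` on the minus strand,
clipped to the chromosome. Protospacer positions are numbered 1
(PAM-distal) to 20 (PAM-proximal); the SpCas9 blunt cut falls between
positions 17 and 18, i.e. 3 bp 5′ of the NGG PAM. `U` is normalised to
`T` on input; candidates containing `N` are excluded from scans.

## Feature registry (27 features)

The registry order is fixed and hashed; trained models store the hash and
refuse to load against a changed registry.

| Group | Features | Notes |
|---|---|---|
| GC | `gc_whole`, `gc_distal_1_10`, `gc_proximal_11_20`, `gc_tail_15_20` | fractions in [0,1] |
| Composition | `freq_A/C/G/T`, `pos20_is_A/C/G/T`, `pos10_is_A/C/G/T` | frequencies + two one-hot blocks |
| Thermodynamic | `tm_wallace_whole`, `tm_wallace_13_20` | Wallace rule, 2·(A+T) + 4·(G+C) °C |
| Structure | `mfe_surrogate`, `stem_fraction`, `hairpin_count`, `longest_unpaired_run`, `seed_unpaired_frac` | from the built-in folding engine |
| Motif | `gg_count`, `tt_count`, `gc_skew`, `purine_fraction` | |

### Folding surrogate

Guide self-structure is computed by a Nussinov-style dynamic program
maximising a weighted pair count (GC = 3, AU = 2, GU = 1, minimum loop
length 3) with traceback. The reported `mfe_surrogate` is the negated
optimal pair score — a dimensionless surrogate, not a thermodynamic free
energy. The Wallace melting temperature is likewise a fast approximation
valid for short oligos. Both are deliberate choices: they are exact,
dependency-free, fully testable against exhaustive enumeration, and used
only as learned features, so their absolute scale is irrelevant.

## Negative-set construction

Published efficient guides are positives; negatives are constructed, not
measured. Within the genomic window of each positive, every PAM-anchored
20-mer (both strands) is aligned to the positive with Smith–Waterman
local alignment (match +1, mismatch −1, gap open −2, gap extend −1; an
identical 20-mer scores 20). Scores below **15** label the 20-mer an
artificial inefficient guide; scores ≥ 15 are excluded as too similar to
carry a confident negative label. Alignment is delegated to Biopython's
`PairwiseAligner`; the test suite checks it against an independent
hand-written Gotoh dynamic program.

## Training pipeline

- **SMOTE**: minority-class points are interpolated along segments to
  their k = 5 minority nearest neighbours until classes balance.
  Implemented in-package (segment interpolation with sklearn
  `NearestNeighbors`); by default applied **inside** each
  cross-validation training fold so no synthetic point derives from
  held-out data. `paper_mode=True` instead oversamples the full dataset
  once before cross-validation — a published-workflow variant that leaks
  neighbourhood information across folds and therefore inflates CV
  scores; it exists for comparability only.
- **Ranking**: XGBoost (200 trees, depth 4, learning rate 0.1, exact
  tree method, fixed seed) total gain orders the features; ties break by
  registry order.
- **Forward selection**: features are added in gain order; for each
  prefix size m ∈ 1..27 an RBF SVM (C = 1, γ = 'scale') is scored by
  mean stratified 10-fold F1; the earliest argmax is kept. Fixing the
  SVM hyper-parameters during selection keeps the curve a function of
  the feature set alone.
- **Grid search**: C ∈ {0.1, 1, 10, 100} × γ ∈ {0.001, 0.01, 0.1, 1} on
  the selected features, same fold structure; best parameters refit on
  all data with standardisation and a sigmoid (Platt-style) calibrator.
  Calibration is monotone in the SVM decision value by construction, and
  verified at train time.
- Degenerate folds (a training fold losing a class) raise an error
  naming the fold rather than silently scoring 0.

## Scoring and design

- **Off-target**: candidate sites within Hamming distance ≤ `max_mm`
  (default 3, hard cap 6) of the guide, adjacent to NGG or NAG, on
  either strand. Each site gets a CFD-style product of per-position,
  per-mismatch-type weights times a PAM weight (NGG 1.0, NAG 0.26).
  Specificity aggregates as `1 / (1 + Σ CFD)`; `mit_like` and `max`
  aggregations are available. The bundled weight table is **synthetic**:
  a linear position ramp (tolerance 0.9 PAM-distal → 0.1 PAM-proximal)
  modulated by mismatch class (rU:dG wobble 0.9, purine–purine or
  pyrimidine–pyrimidine 0.6, other 0.4). It reproduces the qualitative
  structure of measured CFD tables but not their values; the CSV loader
  accepts a measured table with the same schema.
- **Composite**: `2·(0.5·p_on + 0.3·specificity + 0.2·location) − 1`.
  The weights are package defaults expressing on-target dominance; they
  are arguments, not constants.
- **Location**: CRISPRi — core promoter 1.0, promoter 0.7, gene body
  0.3, downstream 0.1, intergenic 0.0. CRISPRko — gene-body thirds in
  transcription orientation 1.0 / 0.9 / 0.7, promoter 0.3, elsewhere
  0.1.
- **Pairs (CRISPRko)**: deletion size (right cut − left cut) must lie in
  [50, 2000] bp; pair score is the mean of the two composites minus
  5·10⁻⁴ per bp outside the preferred 200–1000 bp band. The band and
  penalty rate are package choices: large enough to remove the
  transcript, small enough to limit collateral deletion; the linear
  penalty keeps ranking continuous at the band edges.

## Synthetic fixtures

The generator plants a known efficiency rule so every pipeline stage has
recoverable ground truth: a guide is efficient iff `pos20_is_G = 1`,
`gc_whole ∈ [0.4, 0.75]`, and `mfe_surrogate ≥ −12`. The folding
threshold −12 is the weakly-folded half of the background distribution of
random guides under the engine's pairing scores (P(rule) ≈ 0.05).
Negatives are drawn stratified: one "near-miss" bucket per rule clause
(guides violating only that clause, quota n_neg/4 each) plus
unrestricted violators, so each clause leaves an individually
identifiable footprint in the labels. Labels are then flipped
independently with probability `label_noise` (default 0.05). All
generators are pure functions of their seed.

Scope: the fixtures simulate sequence-driven labels only — no screen
readouts, no chromatin context, no cell-type effects.

## Numerical choices

- All randomness flows through explicitly passed integer seeds
  (`numpy.random.default_rng`, sklearn `random_state`, xgboost seed).
- Undefined metrics (precision with no positive predictions, etc.) are
  `None` with a recorded reason, never silently 0.
- Min–max score normalisation refuses all-equal inputs rather than
  dividing by zero.
- Model files store a format-version tag and the feature-registry hash;
  both are checked on load.

## Limitations

- The on-target models here are trained on synthetic data in the tests
  and examples; applying the package to real designs requires training
  on measured lncRNA guide datasets, and the benchmark-reproduction test
  stays failing until those supplementary tables are supplied locally.
- The bundled off-target weight table is synthetic (see above); absolute
  specificity values should not be compared against tools using measured
  CFD weights.
- Off-target enumeration considers mismatches only (no DNA/RNA bulges)
  and the NGG/NAG PAMs of SpCas9.
- The folding engine ignores stacking energies and pseudoknots; its
  output is a feature, not a structure prediction.
- Single-exon gene models only: no splice-aware targeting, no isoform
  handling.
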