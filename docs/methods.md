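# Methods

## Feature representation

A protein sequence is mapped to the seven-group reduced alphabet (side-chain
dipole and volume classes; group indices are 1-based so encoded strings read
exactly like the descriptor literature prints them).  The sequence is split
into seven near-equal segments; when the length is not divisible by seven the
remainder residues go to the earliest segments (any fixed rule works — this
one is conventional and is frozen so feature vectors are reproducible).
Regions are all 27 contiguous segment runs except the full-sequence run.
The binary segment-inclusion view admits 2⁷−2 = 126 codes (all-zeros and
all-ones excluded), of which only the contiguous ones are used; the
full-sequence run is the one contiguous code additionally dropped, because
whole-sequence information is already carried by the global amino-acid
composition block and 27 × 63 = 1701 is the dimension the local descriptor
must have.

Per region the 63 descriptors are composition (7), transition (21, unordered
group pairs in lexicographic order) and distribution (35).  The distribution
quantile index for a group with c occurrences is round-half-up(q·c) clamped
to [1, c], with the first descriptor the first occurrence and the fifth the
c-th: this rule simultaneously reproduces all fifteen distribution values of
the fully worked 21-residue example for groups 1, 3 and 7, and is the only
rounding rule that does.

C/T/D values are stored as percentages (0–100) and the global amino-acid
composition as fractions (0–1); the unit mismatch is removed by the min-max
scaling step in front of the classifier, so the stored vectors stay directly
comparable with printed descriptor values.

Nonstandard residues: the default `reject` policy refuses them (training-
grade data should be clean); the `map` policy sends U→7 (cysteine's group),
B→6, Z→6, J→2, O→5 and drops X with a logged warning, enabling runs on real
proteomes.  Sequences must be at least twice the segment count (14 residues)
so every region has the two residues the transition descriptor needs;
negative-set filtering additionally enforces the 50-residue minimum.

## Classifier

The ELM hidden layer draws weights and biases i.i.d. uniform on [−1, 1]
(the reference convention for ELMs; the choice only matters jointly with
input scaling).  Inputs are min-max scaled to [0, 1] per feature with
statistics from the training split only — random projections are
scale-sensitive, and fitting the scaler inside each cross-validation fold
keeps the protocol leakage-free.  Output weights solve min‖Hβ − T‖ via
SVD-based least squares (LAPACK gelsd), which returns the minimum-norm
solution when H is rank-deficient (L > N or collinear hidden units).  An
optional ridge term (default 0) switches to (HᵀH + λI)⁻¹HᵀT for
ill-conditioned problems.  Targets are ±1, threshold 0, so the raw scores
feed the ROC/AUC machinery directly.  The default hidden-layer size is
max(1, round(0.09·N)) — nine percent of the training samples, the sizing at
which validation accuracy was observed to saturate for this representation.
Available activations: sigmoid (default), hardlim, gaussian, sine,
triangular basis.

## Evaluation

Confusion-matrix metrics follow the standard definitions; a metric whose
denominator is zero is reported as NaN, never coerced to 0, so fold averages
are not silently inflated (`nanmean`/`nanstd` aggregation, sample n−1
standard deviation, labeled as such in output).  AUC uses the Mann–Whitney
rank form with average ranks on ties — equivalent to the concordant-pair
fraction with ties counting one half.  Cross-validation is stratified
k-fold (default 5) with per-fold refitting of scaler and model; each fold's
hidden layer gets a seed derived from the run seed so folds are independent
but the whole run is reproducible.  A stratified 80/20 holdout helper
supports hidden-neuron sizing sweeps.

## Synthetic data

The generator emulates what the feature pipeline assumes about real
interactomes: proteins with distinct composition signatures (latent classes
with Dirichlet(0.5) residue profiles, mixed with the uniform profile in
proportion `signal_strength`), subcellular compartments for negative-pair
construction, and an interaction rule (a symmetric class-compatibility
matrix drawn from the seed) that is detectable from composition features.
Positives join compatible classes; negatives join incompatible classes in
different compartments — the compartment constraint mirrors how real
negative sets are built, and the class constraint keeps labels consistent
with the planted rule so the recovery test is sharp rather than noisy.
Defaults are 600 proteins of 50–2000 residues over six compartments and
1,000 + 1,000 pairs, at which the full cross-validated pipeline runs in
well under a minute.

What the generator does **not** emulate: residue order beyond i.i.d.
sampling (so transition/distribution blocks carry no planted signal — only
composition and the global AAC do), realistic network topology (no degree
distribution, hubs or modules), homology between proteins, and the class
imbalance of real candidate screens.  Passing the recovery tests therefore
shows the pipeline detects composition-borne interaction signal end to end;
it does not certify performance on real interactomes, where signal is
weaker and partly order-borne.

## Numerical choices and degenerate inputs

- Composition of an empty fragment and transition of a single-residue
  fragment are errors, not zeros.
- Groups absent from a fragment contribute zeros to C and D; transitions
  involving absent groups are zero (forced by the formulas).
- Internal coordinates are 0-based half-open; all user-facing positions and
  region labels are 1-based inclusive.
- Pair identity is the unordered ID pair; self-pairs and duplicate pairs are
  dropped at read time with logged counts.  Pair vectors are ordered A-then-B
  as listed in the input; no symmetrization is applied by default.
- Model archives (npz with a JSON metadata entry) round-trip bit-exactly;
  scores of a reloaded model equal the original's exactly.

## Limitations

- Real-interactome benchmarks (curated positive sets, database-derived
  negative sets) are out of scope; the package ships no downloaders.
- The classifier is binary, single-output; no kernel or sequential ELM
  variants, and no SVM baseline.
- Negative-pair sampling assumes compartment annotations are trustworthy;
  proteins lacking annotations pass the filters in lenient mode, which can
  admit fragments into negative candidates if the input is unannotated.
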