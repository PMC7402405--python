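# Methods

This note documents the models and procedures implemented in `phoglysite`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make results
reproducible.

## Problem setting

Candidate sites are all lysines of a protein collection.  Each site is
described by two per-residue input profiles produced upstream (by
PSI-BLAST and a SPIDER2-class structure predictor for real data; by the
generator here): an L×20 matrix of amino-acid substitution probabilities
and an L×8 table of structural properties.  Labels are binary
(modified / unmodified) and extremely imbalanced — the benchmark shape this
package is modeled on has 111 positives among 3360 lysines (1:29).

## Segmentation and the mirror effect

Windows of half-width 3 (structural) and 20 (evolutionary) are cut around
each site.  Out-of-range indices are reflected back into the protein
iteratively: with the default `exclusive` convention, index i < 1 maps to
2 − i and i > L maps to 2L − i, i.e. reflection about the terminal residue
*without* repeating it.  An `inclusive` convention (0 → 1, L+1 → L,
repeating the terminal residue) is available because the literature is not
unanimous on which variant "mirror effect" denotes; the two differ only in
the padded rows.  Reflection is applied repeatedly, so proteins shorter
than the window (down to L = 2) still yield full-width windows.  A
single-residue protein cannot be mirrored exclusively and is rejected.

Consequences tested as invariants: windows always have exactly 2f+1 rows,
the center row is the site itself, every padded row duplicates a real
profile row, and for interior sites the window is the identity slice.

## Feature construction

* Structural block (56): the 7×8 window flattened position-major
  (offset −3 first; per-position property order asa, pc, pe, ph, phi, psi,
  theta, tau).  The order is fixed by the feature column names
  (`struct_pos{offset}_{property}`), making the layout auditable in any
  written feature CSV.
* Bigram block (400): B = Mᵀ₍₁..₄₀₎ M₍₂..₄₁₎ computed as a single matrix
  product, flattened row-major (`bigram_{p}_{q}` over the PSI-BLAST
  alphabet order `ARNDCQEGHILKMFPSTWYV`).  Because the parser renormalizes
  every profile row to sum exactly to 1, the bigram block of every site
  sums to exactly 40 (one per consecutive row pair) up to float error;
  the suite asserts 1e-9 and the vectorized product is checked elementwise
  (1e-12) against a literal double-loop transcription.

Angles enter raw in degrees.  No sin/cos encoding is applied, so the ±180°
wrap is a discontinuity: two nearly identical backbone conformations can
have τ = 179° and τ = −179°.  This is accepted for fidelity to the feature
definition; the standardization downstream does not repair it, and users
sensitive to it should encode angles trigonometrically before the SVM.

No scaling happens at the feature layer; feature files on disk hold the
raw values.  Standardization is owned by the consumers (cleaning and SVM),
each fitting its own parameters on exactly the data it sees.

## Imbalance cleaning

A negative is removed when at least one of its k nearest other samples is
positive; positives are never removed.  Distances are Euclidean on
z-scored features (z-scores fit once on the table being cleaned; raw-scale
distances would be dominated by ASA and angles over probabilities).
Neighbor ties break by ascending sample index; the query sample is
excluded from its own neighborhood.  Removal is batch: all negatives are
flagged against the same table, then removed simultaneously, so the result
is independent of sample order.

Escalation starts at k₀ = ⌊n_neg / n_pos⌋ and raises k by `k_step` until
n_neg ≤ 2.05 · n_pos.  The 2.05 target encodes "about twice": the
escalation this models stopped at 226/111 ≈ 2.036, which a strict 2.0
would reject.  Two escalation semantics exist:

* `requery="original"` (default): every k is evaluated against the full
  input table.  Since a negative's nearest-positive distance never changes
  (positives are never removed), the survivors at k are exactly the
  negatives whose nearest positive has rank > k — survivor sets are
  monotone in k and the final table equals a single cleaning pass at the
  final k.  Implementation-wise this reduces to computing each negative's
  nearest-positive rank once, so escalation costs one distance matrix.
* `requery="current"`: each k is applied to the survivors of the previous
  round.  This was found to be structurally unstable: removing negatives
  empties the neighborhoods of the remaining ones, which removes more
  negatives at the same k, a positive feedback that collapses the negative
  set far past the target (observed: 3076 → 1 negatives within a few k
  steps on benchmark-shaped data).  It is kept as an option for
  sensitivity analysis but is not the default.

If k reaches the table size or `k_max` before the target ratio, the
best-so-far table is returned with `target_reached=False` in the report —
this is the expected outcome when the classes are (nearly) separable, in
which case distant negatives simply have no positive neighbors at any
feasible k.

Cleaning the whole table before cross-validation reproduces the protocol
this pipeline is modeled on, but lets the cleaning see data that later
serves as test folds.  `clean_within_folds=True` instead re-runs the
cleaning inside each training partition, leaving held-out folds untouched;
both modes are exposed and the default is the historical protocol.

## Classifier

C-support-vector classification with a polynomial kernel, C = 1, γ = 1
(the reference configuration), degree 3 and coef0 = 0 (the customary
library defaults for the two parameters the reference leaves unstated),
all exposed.  Features are z-scored with parameters fit on the training
partition only; whether the original protocol scaled features is unknown,
so scaling can be disabled.  Predicted label is 1 exactly where the
decision score is ≥ 0, so ROC analysis and thresholding are consistent by
construction.

## Evaluation

Sensitivity, specificity, precision and accuracy are the standard
confusion-matrix ratios; MCC is
(TN·TP − FN·FP) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)).  A vanishing
denominator yields NaN ("undefined"), never 0, and undefined per-fold
values are excluded from cross-fold means with a logged warning.  AUC is
the normalized Mann–Whitney statistic (ties ½), computed from average
ranks and verified in tests against an all-pairs count and against
scikit-learn's `roc_auc_score`.

Cross-validation uses stratified folds by default (with ~100 positives,
unstratified 10-folds can lose a class; unstratified remains available)
and aggregates as the unweighted mean of per-fold metrics; pooled
confusion-count aggregation is available behind a flag.  Fold assignment
is seeded, and the pipeline derives its CV seed from the global seed by a
fixed offset so stages are independently reproducible.

The coil/strand analysis reports |Pearson r| between the pc and pe
features for positive rows, negative rows and all rows.  Which window
position's columns are correlated is a free choice; the central (site)
position is used by default and the offset is an argument.

## Synthetic data

The generator emulates the statistical shape of the inputs, not their
biology:

* sequences uniform over the 20 amino acids (a lysine is planted if none
  occurs), so lysine density is ~1/20;
* PSSM rows from a symmetric Dirichlet (concentration 1), renormalized;
* structural rows with Dirichlet(1,1,1) coil/strand/helix triples,
  gamma(2, 40) ASA (mean 80 Å², right-skewed like real exposure values)
  and independent uniform angles in [−180°, 180°];
* class signal: within ±3 residues of a positive site, PSSM rows are mixed
  with `effect_size` units of uniform mass on the residue subset D/E/S/T
  and the coil probability is shifted up by `effect_size` (triple
  renormalized).  At `effect_size = 0` the construction is label-free, so
  positives and negatives are exchangeable — the basis of the null
  calibration test.  The signal lives in both feature families so either
  branch can be ablated.

Defaults (91 proteins, lengths 100–1300, 1:29 ratio, effect size 0.3)
emulate the benchmark shape: ~3.2k candidate lysines, ~106 positives,
initial k = 29, and a cleaning escalation that terminates near the 2:1
target.  The effect size was set once to the regime where the classes
overlap partially: much larger and the classes separate (cleaning then
correctly stalls above the target because distant negatives have no
positive neighbors); zero and there is nothing to learn.

What the generator does **not** emulate — hence what green tests do not
show about real data: amino-acid composition bias and sequence motifs,
autocorrelation along the chain in either profile (real PSSM and
structure predictions are strongly locally correlated), the coupling
between secondary structure, exposure and angles, and database-search
artifacts of real PSSM pipelines.  One emergent artifact is realistic and
worth knowing: windows of *negative* sites that lie within ±20 residues of
a positive site contain signal-bearing rows, which caps attainable AUC as
positive density grows — the signal-recovery tests therefore use sparse
positives.

## Numerical conventions

* PSSM parsing divides the percentage block by 100 and renormalizes each
  row to sum exactly to 1; files written by this package print the block at
  full float precision (unlike PSI-BLAST's integers) so read(write(x))
  recovers x to ~1 ulp.
* Structural and feature CSV readers use round-trip float parsing, so
  write→read is exact on values.
* All randomness flows through seeded `numpy` generators; pipeline stage
  seeds derive from one global seed by fixed offsets.  Two runs with the
  same seed produce byte-identical JSON artifacts.
* JSON serialization maps NaN (undefined metrics) to `null`.

## Problem sizes

The test suite and the acceptance script run the full method at the
benchmark shape (~3.2k sites, 456 features) and smaller calibration shapes
(~200–950 sites) chosen to keep the complete suite in the low tens of
seconds on one CPU; the brute-force oracles (double-loop bigram, full
distance-matrix cleaning, all-pairs AUC) run on inputs small enough that
their quadratic/quartic cost is negligible.

## Known limitations

* Real CPLM-derived benchmarks, PSI-BLAST and SPIDER2 execution, and
  sequence-redundancy filtering are out of scope; the package consumes
  their outputs.
* The cleaning-before-CV default shares information between cleaning and
  test folds, as in the protocol it reproduces; use
  `clean_within_folds=True` for a leakage-free estimate.
* Angles are raw degrees (wrap discontinuity, above).
* `requery="current"` escalation is unstable by construction and kept only
  for sensitivity analysis.
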