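# Methods

This note records the modeling assumptions, numerical conventions and
design choices behind mixqspr, at the level of detail a maintainer or
reviewer needs to interpret its outputs.

## Model family and assumptions

The response of a binary mixture (the motivating case is DES density in
g/cm³) is modeled as an ordinary least-squares linear function of
molar-fraction-weighted mixture descriptors plus temperature and halide
indicators. Two mixture forms are built per base descriptor: the weighted
sum `d_pmix = x1·D1 + x2·D2` and the weighted absolute difference
`d_nmix = |x1·D1 − x2·D2|`. Both are invariant under jointly swapping
component labels and mole fractions; `d_nmix` is non-negative by
construction. Descriptors enter the regression on their raw scales — no
standardization — so coefficients are directly interpretable against the
descriptor units; z-scoring is applied only inside Euclidean-distance
computations (similarity thresholds, consensus neighborhoods).

Mixture identity includes the molar ratio, rounded to 4 decimals by
default: the same chemical pair at 1:1 and 2:1 is two mixtures. The
rounding precision is configurable; 4 decimals distinguishes all common
preparation ratios while absorbing floating-point noise.

Halide indicators are read from the input table, not inferred from
structures, because the package consumes descriptor tables rather than
structures. Mole fractions must sum to 1 within 1e−6 (they are then
renormalized exactly); larger discrepancies are data errors, reported
with the row number.

## Data divisions

Unique mixtures (MO) or unique per-slot chemicals (CO) are sorted by
instance count, descending, with ties broken by first occurrence so the
order is reproducible from the input file alone. The element at sorted
position 0 is always kept in training; the test side is taken at
positions `seed+1, seed+1+interval, …`. Seed is therefore a 0-based
offset after the protected top element — printed split tables elsewhere
use seed values starting at 0, and this convention preserves the two
contracts that matter: the most-populated element always trains, and the
division is a pure function of (seed, interval). The grid runs seeds
0..max_seed and intervals 1..max_interval; coinciding divisions are
merged, keeping the provenance of every generating pair.

In CO, a selected chemical pulls **all** its records to the test side
even when its partner chemical was not selected, so selected chemicals
are entirely unseen during training. A chemical's instance count is its
record count. The ≥ 20 % test-size filter is applied to the merged
division, on record counts.

## Selection and stopping

The correlation prefilter removes, for every pair with |Pearson r| above
the cutoff (default 0.95) on the training rows, the later column in a
deterministic greedy scan over column order. Constant columns must be
dropped beforehand (`drop_degenerate_columns`, variance floor 0 by
default) since their correlation is undefined.

Forward selection proposes, at each step, the candidate maximizing the
configured score: R², negative MAE, or negative mean Poisson deviance
`−(1/n)Σ 2[y·ln(y/ŷ) − y + ŷ]` (the standard deviance form; it requires
strictly positive observed and predicted values). Scores are evaluated
in-sample ("no CV") or as the mean held-out score over k contiguous folds
of a seeded permutation (seed recorded in the trace; the fold assignment
convention is the package's own, documented choice). Ties go to the
lowest column index.

The proposal is accepted only if the leave-one-out MAE of the grown model
is at most `(1 − pct/100)` times the current model's; the reference for
the first step is the intercept-only model, whose LOO prediction for each
point is the mean of the others. The first rejection terminates
selection. A reduction requirement of exactly 0 disables the rule
entirely, giving plain greedy selection truncated only by `max_steps` —
this also makes re-running with a larger `max_steps` a pure prefix
extension. LOO residuals use the exact hat-matrix identity
`e_i/(1 − h_ii)` rather than n refits; tests verify equality with the
naive loop to 1e−12.

## Validation conventions

* **Leave-chemical-out.** Each unique component-1 chemical is removed
  with all its records, the model is refit on the remainder with the
  *frozen* feature set, and the removed records are predicted; likewise
  for component-2. Q²_LCO is the mean of the two Q²-style terms, each
  benchmarked against the fixed full-training mean; MAE_LCO is the mean
  of the two absolute-error sums, each divided by the full training size
  N. Freezing the features (no reselection inside the removal loop)
  matches standard QSPR reporting practice; it is noted as a limitation
  relative to fully nested selection. A removal that leaves too few
  records to refit is an error unless explicitly skipped.
* **External metrics.** Q²_F1 uses the *training* mean in the
  denominator, so the train-mean predictor scores exactly 0. %AARD
  divides by the observed value, which is safe because strictly positive
  responses are enforced at read time.
* **rm² metrics.** r² is the squared Pearson correlation; r0² is the
  determination coefficient of the least-squares line through the origin
  (observed on predicted, and the axes-swapped variant);
  rm² = r²(1 − √(r² − r0²)) with a negative radicand clamped to 0 and
  logged. Default is raw values; min–max scaling of both vectors to
  [0, 1] before the regressions is available via `scaled=True`, since
  the scaled variant exists in the validation literature and the choice
  is not universal.
* **Y-randomization.** The response is permuted per run (seeded,
  bit-reproducible), the same feature set refit, and
  cR²_P = R·(R² − mean R_r²) reported by default; the literature variant
  √(R²·(R² − mean R_r²)) is available as `variant="sqrt"`. Reports name
  the variant used. Values above 0.5 are read as robust against chance
  correlation.

## Applicability domain

Leverages are computed from the intercept-augmented training design;
h\* = 3(p+1)/n. Standardized residuals divide by the training residual
standard error with n − p − 1 degrees of freedom; test/external records
are standardized on the *training* error scale, a documented convention
(externally studentized variants are out of scope). The similarity
threshold is mean + 3·SD (sample SD, n − 1) of pairwise Euclidean
distances in z-scored feature space, with zero-variance features excluded
from the distance and logged.

## Consensus

"Qualified" is not a universally defined notion; the package's predicate
is: the test record lies within the member's leverage domain (h ≤ h\*)
**and** within the similarity threshold of the training set in the
z-scored union-of-member-features space. If no member qualifies for a
record, all members are used and the event is logged. CM2 weights are
proportional to the inverse of each member's cross-validated MAE over the
`n_similar` (default 10) nearest training records; members with zero MAE
share uniform weight. CM3 ties break toward the lower member index. By
default member LOO errors are obtained by refitting each member's feature
set on the supplied training matrix; ensembles whose members come from
different data divisions should pass `member_loo_errors` from their own
validation history.

## Synthetic data

The generator emulates the structure of an experimental DES density
compilation: `n_comp1` HBAs × `n_comp2` HBDs × molar ratios × a
temperature series, with descriptors drawn as independent Gaussians with
per-descriptor random location (1–5) and scale (0.3–1), and a response
that is exactly linear in a small set of weighted-mixture features plus
temperature, with additive Gaussian noise. Defaults — 8 × 6 chemicals,
ratios 1:1 and 2:1, five temperatures from 283.15 to 363.15 K (480
records), intercept 1.10 g/cm³, temperature coefficient −5·10⁻⁴ g/cm³/K
(density falls with temperature), noise SD 0.005 g/cm³ (≈ 0.4 % of
signal) — give a desk-scale dataset of the same order as real
compilations. Most generated acceptors are flagged chloride, some
bromide, some halide-free.

Because the generating law is inside the fitted model family, passing
recovery tests shows the selection/validation machinery is correct, not
that real DES density is this simple: real data have correlated
descriptors, curvature in T, chemistry-specific effects and
heteroscedastic noise, none of which the generator emulates. The external
generator can introduce new chemicals, optionally with shifted descriptor
distributions to create deliberate extrapolation (structural outliers).

## Problem sizes used in the standard checks

The packaged checks run at desk scale, chosen to exercise every code
path: recovery uses 50 generator replicates at the default 480-record
conditions; split contracts are asserted exhaustively on a 5 × 4-chemical
dataset over a seed/interval grid of 5 × 4; the grid driver runs
seeds 0–3 × intervals 1–3 for both strategies; consensus behavior uses 20
replicates of a two-regime fixture. Oracle-equivalence checks use ≤ 30
records and ≤ 10 features, where brute-force enumeration is exact and
fast.

## Known limitations

* Descriptor computation is out of scope; the package consumes
  precomputed per-component descriptor tables.
* Only binary mixtures are supported.
* Feature selection is not nested inside LOO/LCO; reported internal
  statistics are conditional on the selected feature set.
* The qualification predicate and CM2 weighting are explicit
  interpretations of informally specified consensus rules; both are
  configurable.
* Points-out splitting (random record-level holdout) is deliberately
  absent: it leaks mixture identity between folds and overstates
  predictivity.
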