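# Methods

## Connectivity model

Per subject the package fits, by independent per-target ordinary least
squares, either the plain VAR(p)

    X(t) = Σₙ A(n) X(t−n) + E(t)

or the modified VAR(p) with a zero-lag term

    X(t) = A′(0) X(t) + Σₙ A′(n) X(t−n) + E(t),   diag A′(0) = 0.

In the modified model, the equation of target region i includes the other
k−1 regions at lag 0 as ordinary regressors (the self term is never a
regressor, so only instantaneous *cross*-correlation, never
autocorrelation, is modeled) plus all k regions at lags 1..p and an
intercept. This is a deliberately simple estimator: no simultaneous-equation
identification is imposed, each row of A′ is a separate regression, and the
fitted coefficients are exactly reproducible from the normal equations
(asserted to 1e-8 in the tests). The residual covariance is the maximum
likelihood estimate E′E/N.

Derived matrices:

* **Causality** (directed): entry (i, j) = Σₙ a′ᵢⱼ(n), the signed sum of
  the lagged coefficients, diagonal zero. From a zero-lag-inclusive fit
  this is correlation-purged Granger causality (CPGC); from a plain VAR
  fit, the naive Granger measure. The signed sum keeps the
  excitatory/inhibitory direction of an influence; an `absolute` flag
  switches to Σₙ|a′ᵢⱼ(n)| when only magnitude matters.
* **Instantaneous** (undirected): (A′(0) + A′(0)ᵀ)/2 with zero diagonal.
  The estimated A′(0) is already nearly symmetric on z-scored data;
  symmetrization makes the undirected reading explicit and matches the
  k(k−1)/2 feature layout.
* **Pearson**: the sample correlation matrix, as the conventional
  functional-connectivity reference.

Why purging works: if x₂ is an instantaneous copy of an autocorrelated x₁,
a plain VAR can only explain the shared variance through lagged terms and
reports a spurious x₁→x₂ edge (measured ≈ 0.7–1.0 on the test
construction); with the zero-lag regressor present, that variance is
absorbed by A′(0) and the lagged coefficient collapses (|CPGC| ≈ 0.01).

**Order selection.** BIC(p) = N·ln det Σ̂(p) + m(p)·ln N over p = 1..p_max,
with a common effective sample N = T − p_max across candidates (so the fit
terms are comparable) and m(p) counting all estimated coefficients
(including intercepts — a constant offset across p that never changes the
argmin). Ties favor the smaller order. Orders are selected per subject;
a `force_modal_order` switch re-fits everyone at the cohort's modal order.

**Preconditions and degenerate inputs.** A fit requires
T − p ≥ k(p + 1) + 5; shorter series raise an error stating the minimum T.
Exactly collinear regions produce a singular design and an error naming the
duplicated pair. If det Σ̂ is not positive in BIC, a 1e-10 jitter is added
with a warning.

## Preprocessing

Nuisance regression (per region OLS residual on demeaned confounds plus
intercept; collinear confound columns dropped with a warning), then a
4th-order Butterworth band-pass, 0.009–0.08 Hz by default, applied
forward–backward (`filtfilt`, reflect padding of three filter lengths) so
the filter is zero-phase — phase distortion would corrupt lagged
coefficients — then per-region z-scoring (sample sd). The order
nuisance → filter → z-score keeps coefficients comparable across subjects;
z-scoring is a config switch (default on) since model fits are scale
equivariant but cross-subject feature comparability benefits from it.

## RCE-SVM classifier

The cohort is split once into a training and a held-out test half by a
seeded stratified half-split (per-class counts differ by at most one; for
30 + 26 subjects this gives 15 + 13 in each half). All feature
standardization (z-score by training-half statistics), clustering and
scoring are functions of the training half alone — a perturbation test
asserts that corrupting the test half changes no cluster assignment or
score.

Each iteration: (1) K-means (k-means++ seeding, 10 restarts, Euclidean
distance on standardized feature profiles) partitions the surviving
features into n clusters; the initial n starts at the feature count and is
decremented until no cluster is empty. (2) Every cluster is scored by the
mean held-out-fold accuracy of a linear SVM (cost C = 1) trained on that
cluster's features over `n_reps` random stratified `n_folds` partitions of
the training subjects (defaults 10 folds, 500 repetitions). (3) The
lowest-scoring ⌈0.10·n⌉ clusters (at least one, never all; score ties
eliminate the smaller cluster id) are dropped, survivors merge, and the
next cluster count is min(n−1, round(0.9·n), surviving features). The loop
ends at one cluster.

The evolving test accuracy recorded at each iteration is that of a single
linear SVM trained on all surviving training features and evaluated on the
test half; since that classifier is deterministic given the split, the mean
over repetitions equals the single evaluation. The best iteration maximizes
test accuracy with ties resolved toward fewer features, and the final
ranking orders its surviving features by their cluster scores.

A `recluster_each_rep` switch implements the literal reading in which the
clustering itself is redrawn every repetition: per-repetition K-means and
fold scoring, scores averaged at the feature level, elimination applied to
a reference clustering drawn from the iteration seed. The default (one
clustering per iteration, repetitions re-draw only the folds) is cheaper
and fully deterministic.

**The inner SVM.** The scoring step trains on the order of 10⁵–10⁶ SVMs per
cohort, each on ~25 subjects and a handful of features. The package
implements the standard dual coordinate-descent solver for the L1-hinge
linear C-SVM (the liblinear algorithm; bias as an augmented regularized
feature, fixed sweep order, stopping at projected-gradient 5e-3 or 60
epochs) compiled with numba, which brings a fit to tens of microseconds.
Tests verify >97% held-out decision agreement with scikit-learn's
libsvm-based `SVC(kernel="linear")` on random problems and that the loose
stopping rule reproduces the fully converged solver's decisions.

**Known property: selection optimism at the best iteration.** Because the
best iteration is chosen as the maximum of the held-out accuracy curve over
~30–45 iterations, the *reported maximum* is upward-biased even though every
individual iteration's accuracy is an unbiased held-out estimate. Under
label permutation the mean of the curve stays at chance (0.45–0.55,
asserted in tests), but its maximum typically lands at 0.55–0.75 for a
28-subject test half, occasionally outside a single-draw binomial band.
Users should read the evolving-accuracy *curve*, not only its peak, and
treat the peak as model selection that would need an outer validation set
for an unbiased estimate.

## Synthetic cohorts

`simulate_subject` draws Gaussian innovations and runs the reduced-form
recursion X(t) = (I − A′(0))⁻¹(Σₙ A′(n) X(t−n) + E(t)) — the generative
form of the fitted model — discarding a 10·p burn-in. Stationarity is
checked on the companion matrix of the *reduced-form* lag matrices
(I − A′(0))⁻¹A′(n), i.e. the recursion that actually generates the data;
a check on the raw lag matrices would not guarantee a finite process once
zero-lag mixing is present. `stable_random_spec` draws a sparse stable base
model (diagonal lag-1 terms 0.2–0.4, off-diagonal density 0.15 at 0.15–0.35
magnitude, a few symmetric zero-lag couplings at 0.2–0.4, redrawn until the
spectral radius is below 0.95) and plants group differences as shifts of
randomly chosen directed lag-1 weights; the base model and chosen paths
depend only on the seed, never on the effect size. Defaults mirror a
realistic resting-state study: 9 regions, 210 time points at TR = 2 s,
30 + 26 subjects, unit innovation sd, and a small between-subject
coefficient jitter (sd 0.02) for inter-subject variability.

`calibrated_spec` expresses planted effects in feature-level units: a
120-subject group-A calibration batch measures each planted CPGC feature's
across-subject sd, and the coefficient shift is set per path to the target
multiple of that sd. The realized per-cohort effect still varies with the
56-subject draw (standard error ≈ 0.28 on a standardized effect), which is
the honest sampling behavior of a study this size.

What the simulator does *not* emulate: hemodynamic response convolution and
its regional variability, scanner drift and physiological noise spectra,
non-Gaussian innovations, and measurement-driven confounds. Passing
benchmarks therefore demonstrate correctness of the estimator and selection
machinery under the model's own assumptions, not robustness to fMRI
artifacts.

## Benchmark problem sizes

The replicate benchmarks (`cpgc.benchmarks`, driven by
`scripts/acceptance.py` and the acceptance tests) use 20 replicate cohorts
at study scale with 50 scoring repetitions per iteration, 100 simulations
for order selection, and 20 seeds for the purging construction — sizes
chosen so the full battery completes in a few minutes on one CPU while
keeping Monte-Carlo error well below the margins being tested. Two findings
from these benchmarks are worth flagging: (a) requiring *all* planted paths
to survive to the best iteration is fragile (~50–75% of replicates), driven
by the minimum-features tie-break selecting 2–4-feature iterations and by
planted signal leaking into correlated features — the accuracy and
baseline-gain properties are robust; (b) the permutation-null
best-iteration accuracy exceeds a single-draw chance band in a minority of
replicates, which is the selection optimism discussed above.

## Numerical and design notes

* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; identical seeds give bit-identical results
  (including the compiled SVM, which uses a fixed sweep order).
* K-means cluster ids are canonicalized by first feature appearance so
  elimination tie-breaks are deterministic.
* Features named `"SRC->TGT"` map to causality-matrix entry
  (row TGT, column SRC); undirected features use `"A<->B"` (zero-lag) and
  `"A~B"` (Pearson).
* Welch's t-test is used for per-feature group comparison, reported with
  raw p-values and an α = 0.05 flag; no multiplicity correction is applied,
  matching the screening (not confirmatory) role it plays here.
* Degenerate zero-variance features are left at zero after standardization
  rather than raising, since eliminated-to-constant features can occur in
  resampled training halves.
* CSV round trips use round-trip float parsing, so written cohorts reload
  exactly.
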