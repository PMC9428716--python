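# Methods

## The model

`tsdfc` classifies subjects from resting-state ROI time series by combining
two descriptions of the functional connectome that are deliberately
different in character:

1. **Temporal (low-order).** Each subject's M-by-N BOLD matrix is cut into
   K = M − L + 1 overlapping windows of length L (step 1), and a Pearson
   correlation matrix W(k) is computed per window — the dynamic functional
   connectivity network (DFCN). The *temporal variability* of ROI i is

       V_i = 1 − mean_{k<l} corr(w_i(k), w_i(l)),

   where w_i(k) is ROI i's connectivity profile in window k (its row of
   W(k) with the self-entry removed). V_i ∈ [0, 2]: 0 for a perfectly
   stable profile, 2 only for perfectly anti-correlated profiles.

2. **Spatial (high-order).** Every ROI pair traces an "FC series" — its
   correlation value across the K windows. The P = N(N−1)/2 series, each
   concatenated across the S subjects used for fitting (length K·S), are
   grouped into U clusters by k-means; correlating the U cluster-mean
   series yields a U×U network whose entries couple up to four ROIs
   ("correlation's correlation"). The network is sparsified by keeping the
   top fraction ρ of edges by absolute weight (signs preserved), and two
   node-wise features are read off: strength (sum of absolute retained
   weights) and the Onnela weighted local clustering coefficient.

The per-subject feature vector concatenates V (N values), strength (U) and
clustering coefficient (U): m = N + 2U features. Lasso
(½‖Y − Fα‖² + λ_FS‖α‖₁, unpenalized intercept, labels ±1) selects features;
a linear SVM (C = 1, not tuned) classifies.

## Cross-validation protocol

Performance is estimated by nested leave-one-out cross-validation. For each
held-out subject, an inner LOOCV over the S−1 training subjects scores every
hyperparameter combination (L, U, ρ, λ_FS); the winner is the combination
with the highest inner accuracy, ties resolved toward the simpler model
(smaller L, then smaller U, then smaller ρ, then larger λ_FS — fully
deterministic). The S−1 inner-fold classifiers, retrained with the winning
combination, then each vote on the held-out subject; the majority label is
the prediction and the mean decision value its score. Ties in the vote go to
the sign of the mean score (exact zero → positive class, logged).

**Leakage control.** By default every data-dependent fit — the k-means
clustering of FC series, feature standardization (train mean/SD), Lasso and
SVM — sees training subjects only. Cluster assignments are indexed by ROI
pair, so the held-out subject's cluster-mean series are computable from a
training-fold clustering without refitting. `pooled_clustering=True` instead
fits the clustering once on the whole cohort, the way cohort-stacked
high-order networks are usually described; this lets the test subject shape
the cluster structure and is provided for comparability only.
Standardization remains train-only in both modes. Leakage-freedom is
asserted in the test suite by corrupting a held-out subject's data and
verifying that nothing fitted in its outer fold changes.

If Lasso selects nothing (λ_FS at or above the null threshold), the single
feature most correlated with the training labels is used so the protocol
always emits a prediction.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| L | window length (scans) | grid {20,30,…,70} | short windows catch fast dynamics but are noisier |
| Δ | window step (scans) | 1 | the count formula ⌈(M−L)/Δ⌉+1 over-counts for Δ>1 when Δ∤(M−L); windows are then enumerated with floor semantics and a warning |
| U | FC-series clusters | grid {300,…,800} | must satisfy U ≤ N(N−1)/2; controls high-order network size |
| ρ | retained edge fraction | grid {0.1,…,0.9} | ranked by \|weight\|; exactly ⌈ρ·U(U−1)/2⌉ edges kept; ρ=0 is rejected |
| λ_FS | Lasso penalty | grid {0.1,…,0.6} | on the ½-scaled squared-loss objective; the solver's per-sample penalty is λ_FS/S |
| C | SVM penalty | 1.0 | fixed, overridable |

Numerical choices: Pearson matrices are symmetrized, clipped to [−1, 1],
diagonal fixed at 1 (the diagonal is never a feature). A constant signal
within a window is an error under the `strict` policy and a zeroed
correlation plus warning under `tolerant` (the cross-validation default,
since short synthetic windows can go flat). k-means uses k-means++
initialization, 10 restarts, tolerance 1e-6, max 300 iterations, all
seeded; threshold ties at the cutoff magnitude retain the lexicographically
smaller ROI pair. Correlations can be negative, and cube roots of negative
triangle products are ill-defined, so strength and the clustering
coefficient operate on absolute retained weights rescaled by the global
maximum (Onnela convention); with uniform weights this reduces to the
binary clustering coefficient. z-scoring uses the sample SD (ddof = 1) —
Pearson correlation is invariant to the choice. A single global seed is
fanned out to named substreams (CRC-derived, < 2³¹) per stage and per fold,
so every stage is independently reproducible.

## The synthetic cohort generator

Real multi-site rs-fMRI is not required for testing: `simulate` draws each
subject from a hidden Markov chain over a small set of SPD correlation
states (geometric dwell; per-scan stay probability 1 − 1/dwell), emitting
zero-mean multivariate normal observations plus independent Gaussian noise.
Group differences are planted two ways: an additive connectivity offset on
a designated edge block (repaired to a valid correlation matrix by
eigenvalue clipping at 1e-6 and unit-diagonal rescaling) and/or a different
dwell time. The generator emulates the property the method targets —
window-to-window correlation change with group structure — and deliberately
omits hemodynamic convolution, physiological confounds, motion, and spatial
autocorrelation of real parcellations. Passing tests therefore demonstrate
that the pipeline recovers planted covariance dynamics, not that it
matches any particular empirical effect size on real scanners.

Two properties of the temporal-variability statistic discovered during
design and worth knowing:

- V is estimated from windowed correlations, so it has a noise floor that
  grows as L shrinks; contrasts must be read against matched window
  lengths.
- "Faster switching → higher V" holds when L is on the order of the fast
  dwell and the slow group is quasi-static within the scan. It is **not**
  monotone in dwell: a slow group that switches once mid-scan decorrelates
  its window profiles strongly, and long windows average fast switching
  into a stable mixture. The packaged fast-vs-slow demonstration therefore
  uses dwell 5 vs 600 scans with L = 10 at M = 140, where Monte-Carlo
  replication shows the ordering holds in ≥ 19/20 replicates.

The bundled "strong effects" test condition is a cohort of 20 subjects
(10 per group), N = 12 ROIs, M = 120 scans, edge offset 0.8, noise SD 0.05,
dwell 5 vs 600, searched over L ∈ {10, 20}, U = 8, ρ = 0.5,
λ_FS ∈ {0.2, 0.4}. These problem sizes keep a full nested LOOCV (which
refits clustering inside every inner fold) to well under a minute while
leaving the planted signal comfortably recoverable (accuracy ≥ 0.9 across
cohort seeds); label permutation drives accuracy back into the binomial
chance band.

## Known limitations

- The high-order stage assumes all subjects share N and K; cohorts with
  heterogeneous scan lengths must be trimmed upstream.
- Feature-weight reports aggregate Lasso coefficients by (kind, index)
  across folds; when the inner loop picks different U per fold, cluster
  indices are not strictly comparable across folds (the usual practice is
  to fix U when interpreting cluster features).
- AUC is computed from the mean ensemble decision scores; other choices
  (vote fractions) would give slightly different curves and are not
  implemented.
- NIfTI volumes are not parcellated here; inputs are already-extracted ROI
  time series in delimited text.
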