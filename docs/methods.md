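# Methods

## Model

Two imaging feature views, X (n subjects × p regions, dynamic-fALFF) and Y
(n × q, gray matter volume), are coupled with a diagnosis view Z (n × 1,
HC = 0 / patient = 1, centered and scaled like every other column).  The
canonical weights (u, v, w) maximize the sum of the three pairwise
projected covariances u′X′Yv + v′Y′Zw + w′Z′Xu under unit-variance
constraints ‖Xu‖₂ = ‖Yv‖₂ = ‖Zw‖₂ = 1, with three penalties:

* an L1 term on each weight vector (individual-region sparsity),
* a group-lasso "brain network" term ‖u‖_bn = Σ_k ‖u_{G_k}‖₂ over a
  partition {G_k}, k = 1..K, of the regions into brain networks (whole
  networks enter or leave the solution together),
* mixing weights α, β ∈ [0, 1] splitting λ1 and λ2 between the network
  and the individual terms (α = β = 0.5 by default; α = β = 0 recovers
  the plain multi-view model MSCCA).

All feature columns are standardized (mean 0, unit variance) before any
solver runs, toggleable with `scale=False`; CCA-type objectives are
translation-sensitive and the unit-variance constraints presume comparable
column scales.  The canonical correlation coefficient (CCC) reported
everywhere is the Pearson correlation of the score vectors (Xu, Yv).

## Algorithm

The objective is minimized by alternating closed-form block updates.  For
the u-block, holding (v, w) fixed,

    u ← (X′X + λ1 α D̄1 + λ1 (1−α) D1)⁻¹ X′(Yv + Zw),

with diagonal reweighting matrices D1 = diag 1/(|u_j| + ε) and
D̄1 = diag 1/(2‖u_{G_k(j)}‖₂ + ε); v and w are updated analogously, and
each block is rescaled onto its unit-variance constraint.  ε (default
1e-6) guards the denominators, which are otherwise undefined at zero —
standard practice for iteratively reweighted schemes.  Systems are solved
by LAPACK factorization with a 1e-10 diagonal jitter fallback, never an
explicit inverse.  Iteration stops when the max-abs change of (u, v, w)
falls below `tol` (default 1e-5) or after `max_iter` (default 100)
iterations; non-convergence returns a result with `converged_ = False` and
a warning.  Initialization is deterministic (all-ones vectors scaled onto
the constraints); a seeded random-normal init is available for robustness
studies.  The sign indeterminacy (u, v, w) ↔ (−u, −v, −w) — a triple flip
leaves every bilinear term unchanged — is resolved by making the
largest-magnitude entry of u positive.

### Constraint handling and descent — three modes

The quadratic terms ½‖Xu‖² in the objective read like soft (Lagrangian)
replacements of the unit constraints, but as an *unconstrained* function
the objective is indefinite whenever near-aligned score directions exist
across the three column spaces (for a = Xu, b = Yv, c = Zw the quadratic
part is ½(|a|²+|b|²+|c|²) − a·b − b·c − c·a, which is negative along
a = b = c); with correlated data it is unbounded below.  The solver
therefore exposes three `constraint` modes:

* `"projected"` (default): the conventional scheme — unconstrained block
  solve, then rescale onto the constraint.  Cheap and effective, but the
  rescaling is not a descent step, so the objective trace can rise by up
  to ~1e-2 relative on strong-signal data.
* `"constrained"`: exact minimization of each penalized block surrogate
  *on* its constraint set, via a trust-region-style secular equation
  (eigendecomposition + root find per block).  Block-coordinate descent is
  then provably monotone; this mode backs the descent test.  Costs one
  O(p³) eigendecomposition per block update.
* `"lagrangian"`: no rescaling.  Only meaningful when the smooth part is
  positive definite; on correlated data it diverges, and it is kept for
  completeness and small-instance analysis.

### Reweighting variants

The group diagonal admits two conventions, selected with `variant`:
`"printed"` uses 1/(2‖U_k‖ + ε) (the conventional published form) and
`"mm"` uses 1/(‖U_k‖ + ε), which makes the implied quadratic surrogate an
exact majorizer of the group norm (the L1 diagonal 1/(|u_j| + ε) is
already majorization-exact given the ½ in the solve).  Descent guarantees
hold for `"mm"`; the default remains `"printed"`.  At their fixed points
both satisfy the stationarity conditions of the ε-smoothed objective.

The projected fixed point deviates from the exact constrained optimum by
an O(λ) angle, because the rescaling ignores the constraint's multiplier.
The fixed-point-versus-generic-minimizer agreement check is therefore run
at the smallest grid value λ = 0.01, where the measured objective gap is
below 1e-4; at λ = 0.1 it is of order 1e-4–1e-3.

### Baselines

* **SCCA** — penalized-matrix-decomposition-style alternation
  u ∝ S(X′Yv, δ)/‖·‖ with soft-threshold S and δ = c·max|X′Yv|, c ∈ (0, 1]
  a fractional threshold level (grid 0.01:0.05:0.5).  If the threshold
  removes everything, the solver warns and keeps the single largest
  coordinate (the least-sparse feasible solution).  Deterministic init
  from the leading singular vector of the cross-product.  Only the first
  canonical pair is computed (no deflation), here and in all solvers.
* **SCCAR** — SCCA whose update directions are augmented by a
  diagnosis-regression pull γ·X′z (resp. γ·Y′z); γ = 0 reduces exactly to
  SCCA.  The original formulation is not publicly printed in full, so
  this baseline is an intent-faithful reconstruction of "linear regression
  combined with SCCA" and is labeled as such.
* **MSCCA** — the α = β = 0 pathway of the main solver (no network term).

## Model selection and evaluation

Nested cross-validation: stratified outer 5-fold (stratification by
diagnosis keeps the class balance; configurable off), repeated 5 times
with different fold seeds.  Inside each outer-training set, an inner
K-fold grid search scores every hyperparameter point by the mean absolute
gap |CCC_train − CCC_validation| and selects the minimizer, breaking ties
by lexicographically smallest parameters; the winner is refit on the
outer-training set and CCC is recorded on the outer-train and outer-test
splits.  The canonical grids are λ ∈ {0.01, 0.1, 1, 10, 100}³ for the
three-view solvers and c ∈ {0.01, 0.06, …, 0.46}² for SCCA/SCCAR.  Weights
from all outer fits are averaged; because every fit already carries the
canonical sign convention, the average is exactly invariant to fold order.
The inner fold count is configurable (`inner_folds`), since only the outer
5×5 structure is canonical.

## Covariate adjustment

Age and gender effects are removed by OLS residualization of every feature
column on [intercept, age, gender], fitted on the full sample by default
(matching the usual "pre-adjusted features" practice); `fit_on` restricts
the fit to a training subset for leakage-sensitive pipelines.  Residuals
are exactly orthogonal to the covariates and the operation is idempotent.
Rank-deficient designs are rejected with the collinear columns named.

## Dynamic fALFF

Windows of `width_s` seconds (default 60) slide in `step_s` steps (default
10) over a units × T series with sampling interval TR; in samples,
L = round(width_s/TR), S = round(step_s/TR), giving floor((T−L)/S)+1
half-open ranges.  Per window, fALFF is the ratio of summed one-sided FFT
amplitude (no taper) over bins with 0.01 ≤ f ≤ 0.1 Hz to the summed
amplitude over all non-DC bins up to Nyquist; the DC bin is excluded
because it encodes the signal mean, not fluctuation.  d-fALFF is the
coefficient of variation (std/mean) of the per-window fALFF values, with
the sample convention ddof = 1 (configurable).  Units with zero mean
window-fALFF yield NaN with a warning.  Maps are divided by the
whole-brain(-mask) mean, making the masked mean exactly 1, and reduced to
ROI features by within-region averaging.  Whether the denominator should
include sub-0.01 Hz content after an upstream band-pass filter is left to
the user via the band limits; the implementation assumes unfiltered-in-band
spectra.

## Classification benchmark

Six feature-selection strategies feed a linear SVM (C = 1, standardized
inputs, decision scores for AUC) under repeated stratified 10-fold CV:
no selection, equal-variance two-sample t-test (threshold tuned over
0.01–0.10 in 0.01 steps by inner-CV accuracy), and top-10-|weight|
selection per modality from each of the four association solvers.
Selection is refit inside every training fold by default — held-out
subjects never influence the selected columns (asserted by a spy-selector
test) — with a `mode="global"` variant that selects once on all data for
comparability with weight-reuse analyses.  ACC, SEN (positive = patient),
SPE and AUC are reported as mean ± sd in percent over the 100
fold-evaluations.

## Correlation analyses

Pairwise Pearson r between selected features of the two modalities with
two-sided p from the exact t-transform; raw p < 0.05 is the default
significance criterion (matching common practice for these exploratory
maps), with an optional Benjamini–Hochberg adjustment.  Symptom-score
correlations use complete cases only (scores may be missing for a subset
of patients) and support Spearman via a flag; Pearson is the default as
the intended analysis is linear.

## Synthetic data

`generate_multiview` draws a latent factor s ~ N(0, 1) per subject, plants
weight vectors supported exactly on the chosen active networks with
magnitudes |N(0, 1)| + 0.5 (bounded away from zero so support recovery is
well-posed), and emits X = latent_corr·s·u′ + noise_sd·E, likewise Y, plus
a diagnosis obtained by thresholding diag_effect·s + N(0, 1) at its median
— balanced classes like a matched case-control design.  It emulates the
low-rank, network-sparse, diagnosis-coupled structure the model assumes;
it does **not** emulate spatial autocorrelation between neighboring
regions, site/scanner effects, heavy-tailed noise, or any true biophysics,
so passing tests demonstrate algorithmic correctness and calibration, not
clinical validity.  `generate_bold_panel` builds BOLD-like series in the
frequency domain from band/amplitude specifications, with optional slow
amplitude envelopes to create genuine across-window variability.
`generate_demographics` produces a young-adult age distribution, balanced
gender, and PANSS-like symptom subscores with a configurable missing
fraction (default 43.5%, i.e. ~108 complete records out of 191 patients).
All generators are pure functions of their parameters and seed.

## Simulation sizes used by the tests and the acceptance script

* Fixed-point and reduction checks: n = 8–40, p ≤ 8 instances.
* Support recovery: n = 400, p = q = 116, K = 15, 2 active networks,
  latent_corr = 0.6, 20 generator seeds; both solvers at
  λ1 = λ2 = λ3 = 10 (the canonical grid value in the sparsity-active
  regime), α = β = 0.5 for the network solver.  Recovery is scored by the
  ROC AUC of |weights| against the true support and by the fraction of
  the top-m selections (m = true support size, i.e. matched sparsity)
  inside the active networks.
* Cross-validated generalization: n = 120, p = q = 12, K = 3, outer 5×5
  protocol, inner 3-fold over a tied-lambda grid
  {0.1, 1, 10} × {0.1, 1, 10} (λ1 = λ2; the simulated views are
  exchangeable), solver tol 1e-4; 8 null seeds, 12–20 signal seeds.
* Classifier null calibration: n = 382 (the matched case-control size),
  averaged over 10 independent label permutations — a single permutation
  of a small sample carries stable chance association, so the ±5-point
  band around 50% AUC is a property of the permutation-averaged null.
* Correlation calibration: 300 null 10×10 panels at n = 200; planted
  ρ = −0.2 at n = 108 over 500 seeds, compared with the analytic
  Fisher-transform power of the two-sided Pearson test.

## Known limitations

* Only the first canonical triple is computed; no deflation.
* The network penalty assumes one shared partition per view; partitions
  may differ between views (`groups_y`) but not within a view.
* The SCCAR baseline is a reconstruction, not a reference implementation.
* The default AAL-116 → 15-network map is a best-effort reconstruction
  assembled from published network memberships (subcortical, auditory,
  attention, default-mode, visual, sensorimotor per hemisphere, one
  cerebellar network per hemisphere, vermis); the exact published
  assignment is not available in full, so users with a definitive mapping
  should supply their own file, which always overrides the default.
* Raw image preprocessing (segmentation, normalization, smoothing,
  nuisance regression) is out of scope; inputs are ROI-level tables or
  unit × time series produced upstream.
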