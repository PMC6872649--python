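# Methods

This note records the models implemented in `gbmscreen`, the conventions and
defaults chosen where several were defensible, what the synthetic-data
generators do and do not emulate, and the package's known limitations.

## Dose–response model

Viability (fraction of vehicle control, dimensionless) over dose D (nM) is
modelled by the four-parameter logistic

    V(D) = bottom + (top − bottom) / (1 + (D/EC50)^h),   h > 0,

so V falls from `top` at low dose to `bottom` at high dose.  Fitting is
nonlinear least squares over pooled replicates, parameterised in
(log10 EC50, log10 h) so positivity is structural and the fit is exactly
equivariant under dose rescaling.  A fixed multistart over Hill slopes
{0.5, 1, 2, 4} × three log-dose EC50 starts guards against local minima;
the optimizer budget is 10,000 evaluations per start with an RSS tolerance
of 1e-10.  Two conventions are exposed:

* **anchored** (default): `top` is pinned to the mean viability at the
  lowest dose and `bottom` to the mean at the highest dose — the convention
  of end-point screen analysis, where the measured extremes stand in for the
  asymptotes.  Only (EC50, h) are free.
* **free**: all four parameters fitted, with asymptote box bounds of twice
  the observed response span.  This is the convention used for parameter
  recovery against simulated ground truth, since anchoring introduces a bias
  whenever the ladder does not reach the true asymptotes.

Fewer than 4 distinct doses or an entirely flat series are errors, not
degenerate fits.

**AUC** is the trapezoidal integral of mean viability over log10 dose,
normalised by the log10 dose range — i.e. a mean viability across the
ladder, comparable across ladders of different spans; lower = more
sensitive.  Off-ladder dose queries interpolate mean viability linearly in
log10 dose (dose–response curves are locally log-linear); extrapolation
outside the ladder is refused.

**Doubling time** comes from OLS of log signal on time,
T_double = ln 2 / rate; a non-positive rate is reported as non-growing with
an undefined doubling time rather than a negative one.

### Precision of EC50 recovery at screen scale

At the emulated screen design (8-dose 2-fold ladder, 3 technical replicates,
additive viability noise σ = 0.05) the median relative EC50 error of the
free fit across heterogeneous panels is ~7–10%.  This is an information
limit of the design, not an optimizer artifact: a dense (EC50, h)
grid-search oracle with exact per-gridpoint linear solves for the asymptotes
reaches the same residuals and the same error, and even repeated fits of a
single mid-ladder curve (bottom 0.2, top 1.0, EC50 300 nM, h = 1.5) show
~10% median error at this noise level.  Only steep curves (h ≳ 2.5) are
localised to better than 5%.  Tests assert both the exact zero-noise limit
and the noisy-recovery level, and the acceptance script reports the measured
value; users should treat single-screen EC50s at this design as order-of-
magnitude-accurate ranking metrics, which is how the stratification stage
uses them.

## Stratification

Percentiles use linear interpolation between closest ranks (the common
statistics/spreadsheet default; no convention is canonical).  Classes are
value < P25 → sensitive, value > P75 → resistant, everything else (cutoff
values included) intermediate, so ties always share a class.  Because the
cutoffs are rank-based, stratification is invariant under any strictly
increasing transform of the metric.  Cross-metric comparison returns the
full 3×3 contingency plus the explicit (line, from, to) shift list.

## Median-effect synergy

Single agents and the fixed-ratio mixture (total dose, as one composite
agent) are fitted with the median-effect linearisation
log10(fa/(1−fa)) = m·log10 D − m·log10 Dm by OLS.  Observations with fa
outside (ε, 1−ε), ε = 0.005, carry unbounded leverage after the logit
transform and are excluded from the linearisation (logged and counted),
mirroring how fraction-affected values of exactly 0 or 1 are conventionally
dropped.  Viability converts to fraction affected as fa = 1 − V with
supra-vehicle viability mapped to fa = 0.

The combination index at effect level fa uses the mutually-exclusive
(two-term) Chou–Talalay form CI = d1/Dx1 + d2/Dx2, where the mixture dose
achieving fa splits into (d1, d2) by the design ratio.  Calls: CI < 0.8
synergism, CI > 1.2 antagonism, the closed middle band — including the
boundary values — addition.  CI_EC50 is CI at fa = 0.5.

## Paired differential expression and utilities

Per-gene paired t on treated − control differences, two-sided p with n−1 df;
technical replicates are treated as the pairs with no pre-collapsing.
Zero-variance differences take their analytical limits (t = 0, p = 1 at zero
mean; p → 0, flagged, otherwise).  q-values default to Benjamini–Hochberg
step-up, which equals Storey's estimator with π0 = 1 and is conservative;
Storey's π0 with the cubic-spline smoother is available behind a flag
because π0 estimation is unstable at few-thousand-gene scale.  Top-n
selection per direction sorts by ascending q, breaking ties by |t|
descending then gene id, and flags exhaustion.  ΔΔCt fold change is
2^−((Ct_t,s − Ct_r,s) − (Ct_t,c − Ct_r,c)).

## Signature derivation and cohort scoring

Genes separating sensitive from resistant cell lines are ranked by Welch
two-sample t (robust to unequal class variances at ~5 lines per class, where
pooled-variance t is fragile); the top n-per-class with the class-favouring
sign of the mean difference take weights +1 (sensitive-up) and −1
(resistant-up).  Gene identifiers match by exact string after uppercasing
and trimming; probe/alias resolution is out of scope, so cohort intersection
can shrink the signature (provenance records requested vs retained per
sign, and an emptied sign class is an error).

Cohort expression is z-scored gene-wise across samples (n−1 sd;
zero-variance genes dropped with a warning).  A sample's score is the
Pearson correlation between its z-profile over the signature genes and the
weight vector; because z-scoring absorbs per-gene affine transforms, scores
are invariant to per-gene rescaling of the raw matrix, and flipping the
weights exactly negates every score.  Calls use the inclusive thresholds
score ≥ θ (sensitive-like) and ≤ −θ (resistant-like), θ = 0.2 by default.
Subtype tabulation flags subtypes with fewer than 5 calls in either class
for exclusion from survival comparison, since a log-rank test against a
handful of samples is uninformative.

## Survival

Kaplan–Meier estimation and the two-group log-rank test are computed through
`lifelines`, with the standard conventions: events precede censorings at
tied times, the median is the earliest time with S(t) ≤ 0.5 (undefined and
flagged if S never reaches 0.5).  The unit tests pin these conventions to
hand-computed product-limit and O−E/variance examples, and calibration tests
check the nominal type-I rate under the null and power ≥ 0.8 at hazard ratio
2.5 with 80 subjects per group.

## Synthetic designs: what they emulate, and what they do not

All generators take a single integer seed; equal seeds give byte-identical
outputs, and zero-noise outputs round-trip exactly through the corresponding
fits.

* **Viability panel** — 18 lines, 2-fold ladder 11.2 → 1433.6 nM, 3
  replicates, additive Gaussian noise on the viability scale clipped at 0
  only (fluorescence may exceed vehicle control).  True parameters per line:
  bottom ~ U(0, 0.5), top ~ U(0.9, 1.1), EC50 log-uniform between one 2-fold
  step inside each ladder end (screens centre the ladder on the expected
  EC50 range), h ~ U(1, 3).  The replicate noise magnitude of resazurin
  assays is not established; σ = 0.05 is a configuration default, not a
  claim.
* **Combination grid** — single agents follow their median-effect curves at
  0.25–4 × Dm; combination rows sit at the same multipliers of the
  Loewe-additive 50%-effect isobole point at the design ratio, with
  component doses scaled by the interaction factor I, so the true CI equals
  I at every effect level.  With equal sigmoidicities the mixture is an
  exact median-effect curve (fa/fu = (μ/I)^m) and the estimated CI equals I
  to machine precision at zero noise; with unequal m the mixture is only
  approximately log-linear and small systematic deviations remain.  Rows are
  duplicated (n = 2), matching standard screen practice.  Because CI error
  is multiplicative, a single noisy grid can miss the generating I by more
  than 0.05 at σ_fa = 0.02; recovery is therefore quantified as the median
  absolute error over 50 independently seeded grids per interaction level.
* **Cell-line expression** — N(0,1) per-gene baselines, N(0, 0.5) replicate
  noise, 50 planted up-genes per class shifted by 3 log2 units: an
  idealisation of microarray class separation used to validate signature
  derivation.
* **Cohort** — 442 samples split 158/145/139 across
  mesenchymal/classical/proneural (largest-remainder rounding of the design
  proportions).  Each sample draws a latent sensitive-like/resistant-like
  class with subtype-dependent probability (0.85/0.80/0.05 for
  proneural/classical/mesenchymal), reproducing the strong
  subtype–signature association of GBM cohorts; signature genes shift by
  ±effect/2 by class (default effect 2 log2 units), backgrounds are N(0,1).
  Survival is exponential with scale 400 days and hazard ratio 2 for
  resistant-like samples; a censor_rate fraction of samples (default 0.2) is
  censored uniformly before the event time.  The cohort carries 41
  sensitive-up and 38 resistant-up signature genes of the 50 + 50 planted in
  the cell-line generator, so a full derived signature intersects down to
  79 genes.

These generators reproduce the *statistical structure* of the real designs,
not their value distributions: real microarray data have heavy-tailed,
correlated genes, batch effects and probe-level noise; real survival is not
exponential and censoring is not uniform; real combination responses need
not follow the median-effect model at all.  Passing tests therefore
demonstrate that the pipeline recovers known ground truth under its own
model assumptions — they do not certify performance on any particular real
cohort.

## Numerical conventions and degenerate inputs

Concentrations are held internally in nM (µM converted on read; mixed units
within one series are rejected).  Result TSVs are written with `%.10g`
floats and the run manifest omits timestamps, so pipeline reruns with equal
config and seed are byte-identical.  Every dropped gene, excluded fa value
and non-converged or non-growing fit is logged.  Validation failures name
the offending field; degenerate inputs that still admit an answer (flat
growth, zero-variance differences, flat z-profiles) return flagged results
instead of raising.

## Problem sizes used in tests and the acceptance script

Parameter-recovery runs use 100-series panels; CI recovery uses 50 grids
per interaction level; stratification oracle equivalence uses 1,000
18-value panels; cohort classification uses the full 442-sample design;
log-rank calibration uses 1,000 null simulations of 50 + 50 subjects and the
power check 500 simulations of 80 + 80.  These sizes give stable estimates
of each quantity while keeping a full run in the tens of seconds on one
CPU core.
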