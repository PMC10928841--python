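# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind `amesbmd`, together with what the synthetic-data
experiments do and do not demonstrate.

## Data model and screening

The canonical input is a long CSV with one agar plate per row
(`compound, method, s9, vehicle, strain, role, conc_ug_per_plate, count,
toxicity_note`). Concentration 0 is reserved for vehicle controls and
treated rows must have positive concentration, so attaching concurrent
controls to an arm is purely mechanical. The expected replicate scheme is
three treated plates per concentration, six vehicle-control plates, and
two positive-control plates; deviations are reported as warnings, not
errors, because historical studies vary.

Positivity is threshold-based: an arm is positive when the arithmetic mean
count at any non-toxic concentration is at least 2-fold (TA98, TA100,
WP2uvrA(pKM101)) or 3-fold (TA1535, TA1537) the concurrent vehicle-control
mean. Two decisions here:

* **The comparison is inclusive** (a ratio of exactly 2.0 counts as
  positive). Reported practice treats 2.0-fold responses as positive, so
  the boundary belongs to the positive side.
* **A single qualifying concentration suffices**; no trend test is
  layered on. The call matrices this produces are pure functions of the
  plate counts and thresholds.

Toxicity is an explicit per-plate annotation (lawn thinning or absence is
judged by eye at the bench); the pipeline never infers toxicity from
counts alone. An advisory heuristic (mean count below 50% of control) is
available behind a flag for screening, but advisory flags never overturn
annotations and are off by default. Toxic concentrations are excluded
both from calling and from the dose-response data passed to BMD
modelling.

## Dose-response model

Plate counts are modelled as lognormal around the increasing branch of
the exponential model family: `ln(count) ~ Normal(ln mu(dose), var)` with

    m1: mu = a
    m2: mu = a*exp(b*x)
    m3: mu = a*exp(b*x^d)
    m4: mu = a*(c - (c-1)*exp(-b*x))
    m5: mu = a*(c - (c-1)*exp(-b*x^d))

* `a > 0` — background response (revertants/plate at dose 0);
* `b > 0` — potency, units dose^(−d); only the increasing branch is
  implemented because the assay endpoint is an increase over control;
* `c > 1` — plateau as a fold of background;
* `d in [1, 4]` — log-steepness. The lower limit prevents infinite slope
  at dose 0, the upper limit prevents degenerate step-like fits; both are
  common practice for this family and are configurable constants in
  `family.D_RANGE`.

The benchmark response is a 100% increase over background (CES = 1.0, a
doubling); the critical effect dose (CED/BMD) has closed forms for m2–m5,
and for the plateau models it exists only when `c > 1 + CES`.

Zero counts (possible in low-background strains such as TA1537) are
replaced by 0.5 before the log transform; the replacement value is a
`FitData` argument.

## Fitting

Plate-level counts — not dose means — enter the likelihood, so replicate
scatter drives the variance estimate and the interval widths. Doses are
scaled by the maximum dose for conditioning; estimates are reported back
in µg/plate.

The numeric search runs only over the shape parameters (ln b per
subgroup, ln(c−1), d): for any shape, the maximizing background is
`ln a = mean(ln y − ln f)` per subgroup and the maximizing variance is
`var = RSS/n` (per subgroup or pooled, according to the scheme), so both
are profiled analytically inside every objective evaluation. This is
exact at the optimum and removes two dimensions per subgroup from the
search. Optimization is multi-start L-BFGS-B: one moment-based start
(matching the observed maximum fold change) plus Latin-hypercube draws
over the bounded box (10 starts, seed 1234 by default; deterministic
reruns).

**Model selection** follows the ladder m1 → m2 → {m3, m4} → m5: a step is
accepted only when twice the log-likelihood gain exceeds the χ² quantile
at 1 − α (α = 0.05) with df equal to the number of extra free parameters.
m3/m4 ties go to the higher likelihood. Warm starts thread each fitted
model upward (m2 started from m1 with b at its lower bound, m3 from m2
with d = 1, m5 from m4 with d = 1), which guarantees the likelihood is
monotone along the true nestings m1 ⊂ m2 ⊂ m3 and m1 ⊂ m4 ⊂ m5. Note
that m2 is *not* mathematically nested in m4 (a convex exponential cannot
be represented by the concave saturating form), nor m3 in m5, so
LL(m4) ≥ LL(m2) and LL(m5) ≥ LL(m3) are empirical regularities of
saturating (plateau-type) data — the kind the BMD stage actually
receives, since only positive, non-toxic arms are modelled — rather than
theorems.

**Combined-covariate fits** share `c` and `d` across subgroups while `a`,
`b` and `var` are subgroup specific by default; each of the three can be
tested for subgroup dependence with an LR test on G − 1 df (shared versus
specific, the other two kept specific). With a single subgroup every code
path reduces exactly to the single fit.

## Profile-likelihood intervals

For the CED interval the model is re-parameterized so the subgroup's CED
is an explicit parameter (`b` is expressed through the CED via the closed
form, which for plateau models constrains `c > 1 + CES`). The two-sided
90% bounds sit where the profile log-likelihood has dropped
χ²₁(0.90)/2 = 1.3529 below its maximum. Nuisance parameters (other
subgroups' potencies, the shared shape, with background and variance still
analytic) are re-optimized at every probe with warm-started continuation;
the crossing is bracketed by multiplicative steps (factor 1.25) and
refined by Brent root finding. An upper bound beyond 100× the top dose is
reported as unbounded.

**Small-sample calibration.** The χ² calibration is the standard
large-sample one, and at the study design used here (6 concentrations ×
3 plates + 6 controls = 24 plates) it demonstrably undercovers: because
the variance is profiled by maximum likelihood, the profile LR for one
mean parameter behaves like `n·ln(1 + t²/(n−p))`, so the 2.706 cut-off
corresponds to |t| ≈ 1.62 on ~21 df — about 86–88% true coverage rather
than 90%, slightly worse for richer models. Simulation at 500 replicates
reproduces this (≈ 86% for an m3 truth fitted with m3). The effect
shrinks as plates are added and is a property of the standard procedure,
which is retained deliberately for comparability with common BMD
practice.

**Model-selection null behaviour.** Because the family is restricted to
increasing responses, `b = 0` is a boundary point: under a flat truth the
LR statistic for m1 → m2 is asymptotically a ½δ₀ + ½χ²₁ mixture, so the
3.841 cut-off yields a null rejection rate near α/2 ≈ 0.025–0.03 rather
than α. Simulations at 500 replicates measure 0.026–0.032. The χ²
criterion is retained (again standard practice); the effective size being
conservative means the ladder under-fits slightly more often than the
nominal α suggests.

## Potency ranking

Entries are ordered by CED ascending (rank 1 = most potent), ties broken
by lower bound then design. Interval overlap uses closed intervals —
shared endpoints count as overlapping, the conservative choice since a
shared endpoint cannot support a claim of different potency. Quartiles
are defined on rank positions (top quartile of N entries = ranks 1 to
ceil(N/4)), matching how "top quartile of the ranking" is used when
summarizing which assay conditions dominate. The potency span is
reported as max/min CED and its log10 ("log units").

## Synthetic data

The generator draws `count = round(exp(Normal(ln mu(dose), sigma)))` —
the same lognormal structure the likelihood assumes (self-consistency is
the point: recovery experiments then test the estimator, not model
misspecification). Defaults, fixed once:

* log-scale σ = 0.15 — Poisson counting variability at typical
  backgrounds (CV ≈ 0.1 at 100 colonies) plus modest extra-Poisson
  scatter;
* strain backgrounds a: TA98 25, TA100 110, TA1535 14, TA1537 8,
  WP2uvrA(pKM101) 55 revertants/plate — realistic historical-control
  magnitudes, configurable presets, not claims about any laboratory;
* dose grid 50–5000 µg/plate in six levels; 3 treated / 6 control / 2
  positive-control replicates;
* `saturating_truth` builds m5 truths with a plateau fold (default 30)
  and the potency pinned so the doubling dose equals a requested CED.

Toxic doses collapse counts by a fixed factor (default 0.1) and annotate
plates with thinning. A negative-binomial variant
(`noise="negbin"`) exists for robustness checks only; it is not the
model the likelihood assumes. Per-arm seeds derive from the master seed
by stable hashing of the design tuple, so subsetting a study grid
reproduces the shared arms.

What the generator does *not* emulate: colony-size distributions, plate
spatial effects, count-dependent variance (strict lognormality means the
CV is dose-independent), between-day control drift, or positive-control
pharmacology. Passing recovery tests therefore demonstrate correctness
of the estimators under the assumed error model, not robustness to real
plate-count pathologies — the residual-diagnostics tables (QQ and
residual-vs-dose) are the tool for judging that on real data.

## Experiment sizes

The packaged experiments use: 1000 random parameter draws for the
closed-form/bisection CED comparison (agreement to 1e-8 relative, observed
~1e-13); 500 replicates for the null selection rate and for profile-CI
coverage at the 6 × 3 design; 200 studies spanning three log units of
CED for rank recovery (Spearman ≥ 0.95, observed ≈ 0.997); 12 fitted
datasets across the potency range for ladder monotonicity. These sizes
keep the full run within a few minutes on one CPU while leaving binomial
noise well inside the stated acceptance bands.

## Known limitations

* Profile intervals undercover by a few percent at the 3-replicate design
  (see above); treat reported 90% intervals as closer to 86–88% at that
  size.
* Only the increasing branch of the family is implemented; decreasing
  dose-responses (true cytotoxic declines) must be handled by the
  toxicity-exclusion step, not the model.
* No litter/cluster random effects, bootstrap intervals, Bayesian BMD, or
  model averaging.
* The covariate scheme shares `c` and `d` across subgroups; strongly
  shape-discordant subgroups should be split rather than combined, judged
  from the per-subgroup fit plots and residual tables.
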