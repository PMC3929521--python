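# Methods

This note documents the models, defaults and numerical choices behind each
module, what the synthetic-data generators do and do not emulate, and the
known limitations.

## Experimental designs

A face-centred central composite design (FCCD) for `k` factors consists of
`2^k` factorial points (all coded ±1), `2k` axial points on the face centres
(axial distance α = 1) and `c` centre replicates: `2^k + 2k + c` runs. With
`k = 2, c = 5` this is the classical 13-run layout (4/4/5). Centre
replicates exist to estimate pure error; `c ≥ 2` is needed for a lack-of-fit
test. Run order is randomized with a seeded generator and recorded alongside
the standard order, so a design is fully reproducible from `(factors,
n_centre, seed)`.

Coded −1/0/+1 levels are labels bound to user-supplied actual levels.
Method-development ranges are frequently asymmetric around the centre (a pH
factor studied at 2.5/3.5/4.0, say), so the coded↔actual map is piecewise
linear on [low, centre] and [centre, high] rather than one affine map. The
consequence: coded 0 always maps to the centre level, and intermediate coded
values interpolate within the corresponding half-range. The inverse map
round-trips exactly.

Screening uses the standard published Taguchi arrays L4, L8 and L9; the
main effect of a factor is the mean response at its top level minus the mean
at its bottom level. Orthogonality (equal frequency of every level pair in
every column pair) is a property of the shipped matrices and is verified by
test, not assumed.

## Response-surface model

The full second-order polynomial in coded units,
`y = b0 + Σ bi·xi + Σ_{i<j} bij·xi·xj + Σ bii·xi²`
(1 + 2k + k(k−1)/2 terms), is fitted by OLS. Fitting is always done on
coded units: on an FCCD the linear columns are orthogonal to the intercept,
interaction and quadratic columns, so linear coefficients equal
`Σ xi·y / Σ xi²` and are unchanged by dropping higher-order terms.
Actual-unit equations, when needed, are obtained by substituting the
coded↔actual map — never by refitting in actual units, which would destroy
this orthogonality. Rank deficiency is detected from the model-matrix rank
before fitting and reported with the names of the aliased terms.

The ANOVA decomposes SS_total = SS_model + SS_residual and splits the
residual into lack-of-fit and pure error, the latter from within-group
scatter of replicated design points (the centre runs on a standard CCD).
For the 13-run, 6-coefficient fit: df_pe = 4, df_lof = 13 − 6 − 4 = 3.
F_lof = MS_lof/MS_pe follows standard orientation: a large F (small p)
means the quadratic model is inadequate relative to replicate noise. Note
that with very tight centre replicates the lack-of-fit test is extremely
sensitive; it should be read together with R² and the residual SD.

### Desirability optimization

Multiple responses are combined with Derringer–Suich desirabilities:
per-response linear ramps (minimize: d = 1 below `low`, 0 above `high`;
maximize mirrored; target: two ramps peaking at the target), clipped to
[0,1], combined as a weighted geometric mean `D = Π d_i^{w_i/Σw}`. D = 0
iff any d = 0 (a hard veto), D = 1 iff every response is ideal, and D is
invariant to goal order and to uniform rescaling of the weights. The
optimizer evaluates a dense grid over the coded square (default 201×201,
step 0.01 in coded units) and returns the exact grid argmax — auditable
against brute-force enumeration, which matters more than speed in a 2-D
coded domain. Bounds `low/high` are the analyst's acceptability limits, in
response units.

## Validation statistics

- Calibration: OLS (optionally 1/x or 1/x² WLS) of signal on concentration;
  R² is the squared Pearson correlation of fitted vs observed; σ is the
  residual SD.
- LOD = 3.3σ/S, LOQ = 10σ/S. σ defaults to the residual SD of a dedicated
  low-concentration calibration line (six standards spanning the expected
  limit region); an SD-of-blank estimate can be passed instead. The
  LOQ/LOD ratio is 10/3.3 by construction.
- Precision = 100·SD/mean with the sample (n−1) SD — replicate QC sets are
  samples, not populations. Accuracy = 100·observed/nominal.
- Acceptance: a QC level fails if %RSD or |100 − %accuracy| exceeds 15
  (20 at the lower limit of quantitation).
- System suitability: k′ = (tR − t0)/t0; plate number in both conventions,
  N = 16(tR/w)² from base width and N = 5.54(tR/w½)² from half-height
  width; USP tailing factor T = w0.05/(2f) at 5% height; resolution
  Rs = 2(tR2 − tR1)/(w1 + w2).
- Comparisons against printed reference tables tolerate last-digit
  truncation, because such tables are commonly truncated rather than
  rounded at the final digit (e.g. 97.625 printed as 97.62).

## Release kinetics

Encapsulation efficiency EE% = 100·(added − free)/added is inferred from
free drug in the supernatant, so EE% + 100·free/added = 100 identically.
Drug loading DL% = 100·drug-in-NPs/NP-weight.

Sampling with replacement (withdraw `Va` mL, replace with fresh medium)
dilutes the vessel at every draw. The corrected concentration
`Cn_corr = Cn + (Va/Vm)·Σ_{i<n} Ci` adds back the withdrawn drug before the
mass conversion `released = Cn_corr·Vm`, and reduces to naive scaling when
`Va = 0`. On mass-conserving input the corrected series is non-decreasing;
values above 100% (+1% tolerance) set a warning flag rather than raising,
since slightly over-full mass balances are common measurement artifacts.

Model fits use each model's linearizing transform — zero-order: Q vs t;
first-order: ln(100 − Q) vs t; Higuchi: Q vs √t — with R² reported on that
transform. The zero-order fit carries a free intercept by default (the
burst term of a burst + sustained profile), with a through-origin option.
Points with Q ≥ 100% are excluded from the first-order transform with a
warning. Time units (hours vs days) are carried on the profile and never
converted silently.

## Non-compartmental PK

Cmax/tmax come from the observed maximum (earliest time on ties). λz is the
negated slope of ln C on t over the terminal window; the default rule
evaluates every suffix of ≥3 positive-concentration points strictly after
tmax and keeps the window with maximal adjusted R² (ties favour more
points), with an explicit (t_lo, t_hi) override. AUC and AUMC use the
linear trapezoid throughout (log-linear-down is a possible extension, not
currently implemented); tails are Clast/λz and Clast·tlast/λz + Clast/λz².
Identities MRT = AUMC0–∞/AUC0–∞, t½ = ln2/λz and AUC0–∞ ≥ AUC0–t hold for
every successful analysis. Concentrations below the assay LOQ are treated
as missing after the first post-dose sample; the zero baseline at t = 0 is
kept. Dose normalization is not applied — the intended comparison is
between same-dose formulation groups. Group comparison is the two-tailed
unpaired Welch t test (Welch–Satterthwaite df); for two constant equal
groups p = 1 by convention. A sparse-sampling mode (one NCA on group-mean
concentrations) is available by passing the mean profile; per-subject
analysis is the default.

## Synthetic data: what it does and does not emulate

Generators are deterministic under a fixed seed and return their
ground-truth parameters, enabling closed-loop recovery tests for every
analysis module.

- Surfaces: exact quadratic + i.i.d. Gaussian noise. Real responses also
  carry run-order drift and heteroscedasticity, which are not modelled, so
  recovery tests demonstrate correctness of the estimator, not robustness
  to instrument drift.
- Plasma profiles: one-compartment, first-order absorption, multiplicative
  log-normal noise (median 1) chosen to keep concentrations positive.
  Defaults ka = 1.5/h, ke = 0.07/h (t½ ≈ 10 h), V/F = 1 L, dose 4 mg,
  sampled at 0, 1, 2, 4, 6, 8, 12 h then daily to 240 h — a rapid-absorption
  profile on the dense-early/sparse-late schedule typical of small-animal
  studies. No between-subject parameter variability (population structure)
  is simulated, only residual noise.
- Release: Q(t) = burst·(1 − e^(−5t)) + k0·t, capped at 100%. The burst
  rate 5/day makes the burst essentially complete within day 1. Defaults
  burst = 10.4%, k0 = 4.64 %/day were chosen so the curve passes ≈15% at
  day 1 and ≈80% at day 15 — the sustained-release pattern the package
  targets.
- Chromatograms: exponentially-modified-Gaussian peaks; τ = 0 is a
  symmetric Gaussian with T = 1, and T increases strictly with τ. Peak
  descriptors (widths at 50%/5% height, leading half-width) are computed
  from the analytic shape by root finding, not from the sampled trace, so
  suitability tests are free of sampling error. The Gaussian "base width"
  uses the 4σ tangent convention. No detector drift, no peak overlap
  deconvolution.
- Calibration: straight line + additive Gaussian noise on the standard
  eight-level 0.040–2.0 µg/mL schedule.

## Numerical choices

- OLS via statsmodels (QR-based); coefficient recovery on noise-free data
  is exact to ~1e-12. Coefficients are kept in full double precision;
  printed comparisons use 3 decimals.
- Desirability grid resolution 201 per axis (coded step 0.01); the
  reported optimum is the grid argmax, so its location is accurate to half
  a step. A finer grid or analytic polish can be layered on if needed.
- λz best-fit rule requires adjusted R² improvement > 1e-12 to switch
  windows, making window selection deterministic under ties.
- Test problem sizes: 500-replicate unbiasedness checks, 61–201 point
  grids, and ≤20 000-point dense quadrature profiles keep the full suite
  under ~10 s while leaving Monte-Carlo standard errors small enough for
  3-SE coverage tests.

## Known limitations

- Only face-centred CCDs (α = 1); no rotatable/spherical CCDs, Box–Behnken
  or D-optimal designs. Grid optimization is implemented for two coded
  factors (the supported FCCD fitting is general in k).
- No stepwise term selection, ridge/Bayesian fitting, or canonical
  analysis of the stationary point.
- Peak metrics start from descriptors; there is no peak
  detection/integration of raw traces.
- Release models are limited to zero-order, first-order and Higuchi; no
  Korsmeyer–Peppas or mechanistic diffusion–erosion models.
- NCA assumes the linear trapezoid; no compartmental fitting or
  bioequivalence statistics.
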