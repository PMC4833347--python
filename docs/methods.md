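# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of the `foundorfly` pipeline.  Units are mm, mg,
s and mm² throughout; no unit auto-detection is performed.

## Morphometric indices

Indices are computed per queen and never from ratios of group means;
group summaries are means/SDs (or medians/IQRs) of per-queen values.

The abdomen (gaster) is modelled as a prolate spheroid with the
measured maximum length `L` and maximum height `H` as **full
diameters**, giving `V = (π/6) L H²`.  The alternative semi-axis
reading, `V = (4π/3) L H²`, would overstate volume eight-fold and is
inconsistent with the magnitude of observed caste-mean drag areas
(≈ 3.5–4.8 mm² at 2.5–5.7 mg abdomens); the diameter convention is
therefore fixed in the code and flagged here prominently.  The drag
reference area is `V^{2/3}`, a size-and-shape proxy proportional to
aerodynamic drag.  Thorax dry mass is accepted as the flight-muscle
surrogate with no correction factor.

## Caste-comparison statistics

Each trait is screened per group with a Shapiro–Wilk test at
α = 0.05; both groups passing routes the contrast to a *t* test,
otherwise to a two-group Kruskal–Wallis test (tie-corrected).  The *t*
test is Welch by default — the pooled-variance variant is available via
a flag, but with unequal group sizes and variances Welch is the safer
default and the choice cannot be adjudicated from summary data alone.
A per-trait transform option (e.g. natural log for FMR) is applied
before the screen and the test; descriptive percent and fold contrasts
always use raw-scale group means, expressed relative to the parasitic
group.

Holm–Bonferroni families are explicit, never inferred: the
morphology-on-abdomen-mass regressions form one family per index across
the four queen types (m = 4), and the endurance analysis forms one
family per method across its three predictors (m = 3).  The step-down
adjustment itself is delegated to
`statsmodels.stats.multitest.multipletests(method="holm")` behind the
`holm_correction` surface.

Colony-average mode collapses every analysis to one data point per
colony, guarding against pseudoreplication from sampling sisters; the
pipeline emits both modes.  Mixed-effects modelling of colony structure
is deliberately out of scope — averaging plus the colony-factor checks
below serve that purpose.

## Flight endurance

Total flight time is the sum of a queen's (≤ 6) tethered bout
durations.  Colony homogeneity is checked per variable with one-way
ANOVA (when every colony group passes the normality screen) or
Kruskal–Wallis, yielding a pool / do-not-pool recommendation at
α = 0.05 before colony identity is dropped from the final fits.

The upper performance envelope is fit by quantile regression at
τ = 0.75.  The check-loss minimization is solved **exactly** as a
linear program (`scipy.optimize.linprog`, HiGHS): with two free
parameters, an optimal basic solution interpolates at least two data
points, which the test suite exploits by comparing the solver's
objective against an exhaustive point-pair search oracle to 1e-9 on
hundreds of small random datasets.  `statsmodels` `QuantReg` (IRLS)
serves as an additional independent cross-check, never as the
implementation.  Degenerate predictors (all x equal) are rejected.

Slope inference uses a seeded xy-pairs bootstrap (two-sided, +1
small-sample correction; resamples degenerate in x are redrawn).  The
reference R implementation defaults to rank-inversion intervals, so
published p-values for such fits are matched only approximately; the
bootstrap was chosen because it is self-contained and exactly
reproducible from a seed.  Predictors (dry abdomen mass, log FMR, wing
loading) are analyzed one at a time, as three univariate fits.

The light-abdomen outlier rule (a just-eclosed queen not provisioned
for flight) only **flags** by default — below an absolute threshold or
more than k = 3 SD below the cohort mean — and excludes only with
explicit assent, logging every reason.  No published exclusion
threshold exists, so the rule is config-surfaced, not hard-coded.

## Tradeoff model

Dry abdomen mass a (mg) maps to:

- maximum flight duration `D(a) = max(6742.350 − 1096.915 a, 160)` s —
  the upper-quartile envelope, floored at 160 s because even the
  heaviest queens routinely manage flights of a few hundred meters.
  The floor-crossing mass is derived from the config (≈ 6.0 mg with
  defaults); durations beyond it are extrapolation.
- speed: constant maximum 1.5 m/s, caste averages 0.9 (parasitic) / 0.6
  (claustral) m/s, or a user-supplied function of live body mass (the
  literature mass–speed formula is not reproduced here, so that mode
  requires a callable).
- range `v·D` (purely horizontal flight) and potential colonization
  area `π (vD)²` in km².
- first-generation workers: by default a **two-point linear
  calibration** through (2.7 mg → 10 workers) and (5.3 mg → 31
  workers), clamped at zero below its root (≈ 1.46 mg).  This is
  explicitly a calibration to reported model outputs, not a derivation:
  the underlying rearing-study formula (on live abdomen mass, live:dry
  = 2) is not published alongside the coefficients, so the pluggable
  interface — any monotone callable of live mass — is the contract.

Headline values follow the printed rounding conventions (duration to
the nearest 100 s before ranges/areas are formed, range to the nearest
m, area to the nearest km²), because the published contrast ratios
(3,800/900 s; 102/6 km² → 17-fold) are only mutually consistent under
that rounding.  Unrounded values are always reported alongside.  Under
caste-average speeds the rounded pair computes to 37 vs 1 km² (36.75
and 0.92 km² unrounded), commonly summarized as "roughly 36-fold"; the
package reports both the rounded-pair ratio and the exact ratio and
does not force either to a headline figure.  Note that with equal caste
masses all duration and worker folds are 1, but caste-average speed
folds remain (0.9/0.6) for range and its square for area — the speed
contrast is a model assumption, not a function of mass.

## Synthetic cohorts

The generator emulates the study design: two species × two castes with
caste-specific trait means/SDs at the study sample sizes (13/38/58/33
queens over 3–6 colonies per cohort).  Each queen is built as a **body
frame plus a variable abdomen** — head width, thorax, wing and residual
(head/legs/petiole) dry masses, forewing length and wing area drawn
independently as truncated-positive normals, body mass their exact sum
— so FMR, wing loading and drag co-vary with abdomen mass
mechanistically rather than being drawn directly.  This is what makes
regression-slope recovery a genuine test: the wing-loading-on-abdomen
slope, for example, must emerge as ≈ 1/(mean wing area) ≈ 0.037 per
mg, matching the published claustral *S. invicta* fit (0.0367) without
ever being programmed in.

Parameter choices:

- Component means for thorax/wing masses are backed out of caste-mean
  FMR and wing-mass density; component SDs scale the dry-mass
  coefficient of variation, since no component-level SDs are published
  beyond the abdomen.
- Abdomen geometry: volume = mass / dry-density; the shape ratio L/H is
  drawn per queen (mean 1.5, SD 0.1, truncated at 1 — a typical gaster
  silhouette), then `H = (6V/(π r))^{1/3}`, `L = rH`.
- Abdomen dry density is a **calibration constant**, not a measurement:
  per caste, density = caste-mean abdomen mass / caste-mean drag^{3/2}
  (0.35–0.53 mg/mm³).  A single shared constant cannot reproduce the
  observed drag contrasts, because parasitic abdomens are effectively
  less dense; the per-caste calibration restores the published caste
  mean drags exactly in the zero-variance limit.  The dataclass default
  (no caste given) is the claustral *S. geminata* value.
- Colony effects are additive normal shifts shared within a colony,
  with SD = 0.2 × trait SD by default (individual SD shrunk to keep the
  marginal SD at spec); small, because colony identity was not a
  significant factor in the flight analyses.

Tethered flights: each queen's latent maximum is
`D_max(a) = max(intercept + slope·a, floor)` with the endurance-envelope
defaults above; the realized total is `D_max × B` with B a sub-maximal
"opportunity" factor in (0, 1].  B is a two-part mixture: Beta(s, 1)
with s = 5 (mass near 1, so the τ = 0.75 conditional quantile sits at
≈ 0.93·D_max and the fitted envelope is nearly unbiased), and with
probability 0.2 a reluctant-flier component Beta(1, s) that keeps
minimum durations short at every abdomen mass — heavy queens can only
fly briefly, light queens fly long or short.  The total is split into
1–6 positive bouts by a uniform Dirichlet draw.  `opportunity_scale =
inf` with zero reluctance forces B = 1 exactly (used by degenerate
tests).  All draws derive from `numpy.random.default_rng` seeds;
replicate seeds are spawned from one master `SeedSequence`.

What the generator does **not** emulate: per-queen covariance between
body mass and wing area (so a zero-variance cohort reproduces
ratio-of-means contrasts, which for claustral-vs-parasitic *S. invicta*
wing loading lands near 58% rather than the published group-mean 55%),
measurement error, seasonal condition differences between castes, and
any spatial or behavioral structure.  Passing tests therefore
demonstrate that the statistical machinery recovers the data-generating
mechanism it assumes — not that real queens obey it.

## Verification strategy and problem sizes

- Quantile solver vs exhaustive point-pair oracle: 200 random datasets,
  n ≤ 8, objectives equal to 1e-9 (plus τ = 0.5 ≡ least absolute
  deviations, the subgradient bracket `#(y<fit) ≤ τn ≤ #(y≤fit)`, and
  never-worse-than-OLS checks).
- Envelope-slope recovery: 100 seeded replicates of 200 queens with
  abdomen masses uniform on 3.5–6.5 mg; the τ = 0.75 slope must fall
  within ±25% of −1096.915 s/mg in ≥ 90% of replicates.  The recovered
  slope is mildly attenuated (≈ −890 on average) by the ≈ 0.93 quantile
  of B and by the floor region above 6 mg — both genuine features of
  the generating model, well inside the band.
- Prolate-spheroid volume vs Monte-Carlo hit counting: 10⁶ points,
  agreement within 1%.
- Scale covariance: mass rescaling moves loadings linearly and leaves
  FMR fixed; length rescaling moves volume as c³, drag as c², aspect
  ratio not at all (property-based, seeded/derandomized).
- OLS agrees with the closed-form normal equations to 1e-10 on random
  3-point inputs.

These sizes keep the full suite under ~20 s on one CPU while leaving
each check statistically meaningful.

## Degenerate inputs and numerical conventions

Constant samples are treated as failing the normality screen; a
contrast between two all-equal groups is reported with NaN statistic
and test label "degenerate" rather than an error.  A constant response
in OLS returns slope 0, r² 0.  IQRs use linear-interpolation
percentiles.  Result CSVs serialize floats at 6 significant digits, so
write → read → write is byte-stable; provenance headers carry stage,
config digest and seed but no wall-clock timestamp, keeping pipeline
outputs byte-identical under a fixed config and seed.  Rounding of
headline tradeoff values is half-up.

## Optional validation against the original data

Specimen-level validation — the per-queen-type regression coefficients
of the indices on abdomen mass, and the exact fitted endurance envelope
(n = 32) — requires the deposited per-queen dataset, which is not
bundled here.  Given a CSV mirror of it in the documented column
layout, `fof morpho` + `fof compare` and `fof endurance --tau 0.75`
reproduce those tables directly; the test suite instead verifies the
desk-scale mechanistic surrogate (the emergent wing-loading slope) and
all published-scale worked numbers.
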