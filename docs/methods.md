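# Methods

## The biphasic recovery model

After a strong photopigment bleach, psychophysical threshold at a retinal
locus recovers in two phases. The cone system recovers quickly, as an
exponential decay from the initial threshold `t0` toward the cone plateau
`ct` with time constant `τ` (minutes). Once rod sensitivity overtakes the
cones — at the cone–rod break `CRB` — detection becomes rod-mediated and
the threshold declines further, linearly in log units at rate `S2`, until
it saturates at the final rod threshold `tf`. The two branches are joined
in intensity space:

    threshold(t) = ct + (t0 − ct)·e^(−t/τ)                                    t ≤ CRB
    threshold(t) = ct + (t0 − ct)·e^(−t/τ) + log10(10^(S2·(t−CRB)) + 10^(tf−ct))   t > CRB

All thresholds are in logUnits; the instrument's dB attenuation maps to
logUnits as `threshold = 2.0 − dB/10`, placing the 36 dB floor at −1.6.

Conventions worth noting:

* `S2` is stored **negative** (threshold falls during rod recovery) so the
  expression above holds verbatim; user-facing reports show |S2| as the
  rod recovery rate.
* `t = CRB` belongs to the cone-only branch. The function therefore has a
  small upward jump of `log10(1 + 10^(tf−ct))` just after the break —
  under 0.014 logUnits whenever the rod plateau sits ≥ 1.5 logUnits below
  the cone plateau, i.e. negligible against measurement noise.

**Rod intercept time (RIT).** The primary dynamic outcome is the first
time the curve crosses −1.4 logUnits, a criterion roughly one log unit
below a normal cone plateau, so only rod-mediated recovery can reach it.
The search is restricted to `(CRB, t_max]`: if an (abnormal) fitted cone
plateau lies at or below the criterion the operation raises a domain
error rather than report a cone-mediated crossing. The curve is strictly
decreasing on that interval, so bracketing plus bisection to 10⁻³ min is
exact for practical purposes; a 0.01-min grid scan is kept as a fallback
for numerically pathological parameter sets. Curves that never cross
within `t_max` = 60 min are censored, with RIT recorded as 60.

## From staircase presentations to outcomes

Each *seen* response of the 5-up/1-down staircase (5 dB dimmer after
seen, 1 dB brighter after a miss) contributes one timestamped threshold
point; misses contribute none. Points at the 36 dB floor are retained but
flagged: thresholds below −1.6 logUnits are left-censored by the dynamic
range, and the fit treats floor points as exact values — a documented
limitation that matters mainly for very low rod plateaus.

**Rod-function detection.** Rods do not detect the 627 nm stimulus at
these light levels, so a rod-mediated locus shows the cyan threshold
dropping below the red threshold late in the session. A locus is classed
rod-intact when, over the final 10 min, the median cyan threshold lies
more than 0.3 logUnits below the median red threshold (both parameters
config-exposed). This automates what is otherwise a manual curve review.
Loci without separation get a cone-mediated FT (= CT) and censored RIT.

**Curve fitting.** Only cyan points enter the fit (red points only feed
the detection rule). The default `map_penalized` mode maximizes a
Gaussian likelihood times truncated-normal priors over a broad
physiological box — ct ∈ [−1.5, 1.5], t0 ∈ [ct, 4.5], τ ∈ (0, 10] min,
S2 ∈ [−1.0, −0.01] logUnits/min, CRB ∈ [1, 45] min, tf ∈ [−3.5, ct] —
with prior centers mid-box and SDs equal to the box half-width: broad
enough to keep solutions physiological without meaningfully influencing
well-determined fits, and identical for every locus. Implementation:
bounded least squares (scipy `trf`) on data residuals plus prior
pseudo-residuals scaled by the noise SD; the noise SD is profiled by one
refit iteration with a 10⁻³ floor, so the noiseless limit reduces to
exact interpolation (noiseless refits recover all six parameters to
≪ 1%). Order constraints are enforced by fitting offsets d0 = t0 − ct ≥ 0
and df = ct − tf ≥ 0. Twelve seeded starts (three data-driven heuristics
plus uniform draws in the box) guard against local minima; the best
objective wins. The `mcmc` mode samples the same posterior (plus log-σ)
with the affine-invariant ensemble sampler and reports posterior medians;
on well-conditioned data the two modes agree within uncertainty (tested).
Fitting requires ≥ 8 cyan points spanning ≥ 15 min. Residuals are modeled
homoscedastic Gaussian in logUnits — the simplest adequate choice.

Curves with no rod branch in the data leave the rod parameters
unidentified; the fit then reproduces a flat curve over the observed span
(the prior parks `tf` mid-box beyond the data) and the rod-function flag,
not the fitted `tf`, decides the reported outcome.

## Normative limits and deviations

For each outcome (CT, FT, RIT) the healthy cohort is modeled as

    outcome ~ intercept + age (per decade) + eccentricity (categorical, 2° ref)
              + subject random intercept + residual

fitted by REML (statsmodels MixedLM; age in decades for conditioning).
The 95% prediction interval for a new subject at a new locus is the
fixed-effect prediction ± 1.96·√(between-subject var + residual var); its
width is constant in age and shared across eccentricities. In the exact
zero-noise limit the mixed model is singular and the fit falls back to
OLS with null variance components. A frequentist REML backend was chosen
over a Bayesian twin because both target the same estimand; the curve
fitting layer retains both penalized-MAP and MCMC backends where the
posterior is genuinely non-Gaussian.

Deviations follow the clinical sign conventions: thresholds as
`predicted − observed` (negative = sensitivity loss), RIT as the delay
`observed − predicted` (positive = slowed recovery). A censored RIT of 60
is compared as-is; when it exceeds the upper limit the recorded delay is
a lower bound and the record is flagged censored. Censored healthy RITs
(rare) are included untransformed in the normative fit by default, with a
config flag to exclude them. Abnormal = outside the two-sided 95% band;
disease moves all three outcomes upward, so the effective test is
one-sided at 2.5%.

## Covariate-adjusted ROC

Because the diseased group is typically older and every outcome drifts
with age, a pooled ROC overstates accuracy. The adjusted estimator
(induced linear model):

1. regress the marker on age among healthy subjects (OLS, Gaussian
   residuals);
2. placement value of each diseased subject = probability that a
   covariate-matched healthy subject is more extreme in the diseased
   direction (survival of the standardized residual);
3. adjusted ROC = empirical CDF of placement values; adjusted AUC
   (AAUC) = exact area under that step function = 1 − mean placement
   value;
4. percentile bootstrap over subjects, stratified by class and seeded,
   for the interval.

This parametric estimator was preferred over semiparametric/Bayesian
alternatives because it is transparent and testable against closed
forms: AAUC = 0.5 under the null, Φ(δ/(σ√2)) for a binormal shift,
equality with the pooled Mann-Whitney AUC when the covariate is
independent of the marker, exact invariance under affine marker
transforms, and AAUC ≈ 0.5 under pure age confounding where the pooled
AUC is inflated — all asserted in the test suite. The reported curve is
sampled on a 101-point false-positive-fraction grid; its trapezoidal
integral matches the exact area to within half a grid cell (the area is
not computed from the grid, so saturation at AAUC → 1 is represented
exactly). Censored RITs enter as 60; under the parametric healthy
reference their placement values remain continuous, so no tie-breaking
is needed. Directions: RIT and both thresholds use "higher is diseased".

## Structure–function regression

Per eccentricity, OLS of RIT on SDD (0/1), study-eye diagnosis, fellow-eye
diagnosis (levels none/eAMD/iAMD/lateAMD, "none" = reference, healthy
controls pooled with patients) and age per decade, with Wald 95% CIs and
t-test p-values, R² and adjusted R². Dummy columns absent from the data
are dropped; a rank-deficient design (e.g. fellow-eye identical to
study-eye for every row) raises a collinearity error naming the aliased
columns. Note that a cohort in which *every* patient has disease in both
eyes and every control none aliases the two severity terms exactly —
identifiability requires some unilateral cases.

## The synthetic study

`generate_cohort` draws 35 healthy volunteers (ages 22–82) and 35 AMD
patients (ages 47–86; 29% with SDD; study-eye severity 31% early / 57%
intermediate / 11% late; fellow-eye severity similar with a 3/35
unilateral "none" fraction that keeps the regression identifiable). Per
locus, targets for CT, FT and RIT are built additively — intercept + age
slope·decades + eccentricity offset + severity effect + SDD effect +
subject random intercept + locus noise — and a ground-truth curve is
solved to hit them: the cone–rod break is obtained in closed form from
the crossing condition at the default rod slope (−0.24 logUnits/min),
clamped to [2.5, 45] min with the slope re-solved when clamped. Targets
at or beyond 60 min yield naturally censored curves. Key defaults, all
config-exposed:

* RIT: healthy intercept 10 min at 2°, +2 min/decade, eccentricity
  offsets 0/−0.5/−1 min; disease effects at 2° of +10/+30/+28 min
  (eAMD/iAMD/late), graded ×1.0/×0.6/×0.35 across 2°/4°/6° (parafovea
  worst); SDD +20 min, macula-wide (ungraded); between-subject SD
  2.5 min, locus SD 1.5 min. A 5-min floor and the 2.5-min break floor
  keep curves physiological — after a ~59% bleach, earlier breaks are
  not realistic and would leave the cone plateau unexpressed.
* CT: −0.85 + 0.025/decade logUnits, disease shifts +0.02/+0.10/+0.15,
  SDD +0.05; SDs 0.12/0.08 — deliberately small so disease expresses
  primarily in rod kinetics (RIT-dominant), as in early disease.
* FT: −2.35 + 0.025/decade, shifts +0.10/+0.50/+0.70, SDD +0.40; SDs
  0.15/0.10. Healthy rod plateaus sit ~0.2 logUnits more sensitive than
  the AMD steady-state medians they anchor to.
* The healthy age slope of 2 min/decade reflects parafoveal testing;
  more eccentric protocols report ~0.6–1.2 min/decade.

`simulate_session` then runs the actual psychophysics in real time:
presentations every 4 s, one 5-up/1-down staircase per (locus, color)
over 0–36 dB, loci visited in ascending eccentricity with colors
interleaved, advancing after each seen response (with a 10-miss
anti-starvation override, since the device's scheduling during long
unseen stretches is not documented). The observer sees with probability
`guess + (1 − guess − lapse)·Φ((stimulus − threshold)/slope)` — slope 0.1
logUnits, lapse 0.02, guess 0.01, conventional psychophysics values —
where the momentary threshold is the biphasic truth curve for cyan and
the cone branch only for red (627 nm detection stays cone-mediated).
Sessions end at 60 min or earlier (never before 20 min) once every cyan
staircase is steady (last five thresholds within 1 dB). Truth RIT is
recomputed with the same root-finder the analysis uses, so generator and
analysis share a single definition; when a late break leaves the rod
plateau unobservable in session, the truth FT carries the cone-mediated
label the analysis rule would assign.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: fixation losses and fundus-tracking
errors, pupil-size and lens-status effects on effective bleach, fatigue
breaks, test–retest variability, non-Gaussian threshold noise, spatial
correlation between neighboring loci beyond the shared subject
intercept, and any photochemistry (bleach strength is metadata only).
Staircase quantization (1 dB), tracking lag during fast recovery, and
the 36 dB floor *are* emulated, and set the realistic error floor seen in
the round-trip tests.

## Numerical and design notes

* All randomness flows from explicit integer seeds (cohort seed; session
  seed = cohort seed + 1; per-subject child seeds via `SeedSequence`);
  equal seeds give byte-identical outputs, and the run-metadata JSON
  records seed, package version and a config hash.
* Fitted FT for severely delayed eyes is intrinsically weakly
  identified: when recovery is still ongoing at 60 min the likelihood is
  flat below the last data and the prior centers `tf` mid-box. This
  depresses FT's discriminating accuracy at 2° in the synthetic study —
  a consequence of fully automated review within a capped session.
* Round-trip accuracy is assessed against the *measurable* truth: FT is
  floor-censored at −1.6 logUnits, and loci whose rod plateau sits within
  ~0.02 logUnits of the RIT criterion are knife-edge cases whose
  censoring status is genuinely unstable.
* Problem sizes in the test suite and acceptance script (one default
  cohort of 70 subjects ≈ 210 loci; 100-replicate recovery studies;
  6–8-replicate estimator checks at n = 400–1000; 200-replicate
  regression coverage) were chosen as the smallest sizes at which
  Monte-Carlo error is clearly below each assertion's tolerance.
* Normative coverage checks train on 200 subjects: at n = 35 the REML
  variance components carry enough sampling error to move empirical
  coverage by more than the ±2% assertion band, which would test the
  cohort size rather than the interval construction.
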