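# Methods

This note documents the statistical models implemented in `catrisk`, the
conventions and numerical choices behind them, what the synthetic cohort
generator does and does not emulate, and the known limitations.

## Setting and data model

One record per patient: baseline demographics, tumor site, pre-treatment
labs, the four ONKOTEV risk factors, and first-event follow-up from the
start of anticancer therapy. Time is in months. The event code records the
*first* event only: 0 = censored, 1 = VTE, 2 = death before any VTE. Deaths
occurring after a VTE are not recoded — the analysis is of the first-event
process, with death acting as a competing risk for VTE.

Two record-level filters reproduce a typical eligibility flow: baseline
anticoagulation and age < 18 are excluded (logged separately), and the
complete-case filter removes any record in which the ONKOTEV score or the
outcome is not computable. A record counts as incomplete whenever *any*
Khorana component is undecidable, even if the Khorana > 2 flag would be
logically forced by the components already known (e.g. a very-high-risk
site plus thrombocytosis forces the flag regardless of BMI). The blanket
rule is simpler, matches the usual complete-case wording of validation
studies, and makes the filter's behaviour independent of the score's
internal arithmetic. The anemia component uses OR-semantics with
three-valued logic: hemoglobin < 10 g/dL *or* use of red-blood-cell growth
factors; if one input is missing but the other already decides the
component, it is decided.

Cell-level problems at parse time (unparseable numbers, BMI outside
(10, 80), hemoglobin outside (2, 25) g/dL) set the value missing and are
counted in a parse report rather than rejecting the file; structural
problems (missing mandatory columns, duplicate patient ids, events at time
zero, negative times) raise. This keeps one bad lab value from discarding
an entire cohort while still refusing structurally broken input.

## Scores

Khorana score = 2·[very-high-risk site] + 1·[high-risk site] + 1·[anemia or
ESA] + 1·[leukocytosis > 11 000/µL] + 1·[thrombocytosis ≥ 350 × 10³/µL] +
1·[BMI ≥ 35], range 0–6. The component thresholds are fixed definitions;
the point weights and the site-risk mapping are configuration
(`ScoreConfig`) with defaults very_high = {gastric/gastroesophageal,
pancreas}, high = {lung, lymphoma, gynecologic, bladder, testicular},
everything else (including unknown primary) low. Unknown site labels map to
low risk with a warning rather than erroring, so one exotic diagnosis does
not stop a cohort analysis.

ONKOTEV score = [Khorana > 2] + [metastatic] + [compression] + [prior VTE],
range 0–4, analysed in the four strata 0 / 1 / 2 / >2 (scores 3 and 4
pooled; the top stratum is small in cohorts of a few hundred patients).
For analyses that need an ordinal marker (the time-dependent AUROC), the
integer score 0–4 is used rather than the pooled stratum.

## Cumulative incidence (Aalen–Johansen)

For cause k at the ordered distinct event times t₁ < t₂ < …:

    F_k(t) = Σ_{tᵢ ≤ t} S(tᵢ⁻) · d_k(tᵢ) / n(tᵢ),

with S the all-cause Kaplan–Meier survivor from the pooled events, d_k the
cause-k events and n the number at risk. Tie convention: events precede
censorings at the same time, and tied events of different causes share the
same risk set. Pointwise variance uses the delta-method (Marubini–Valsecchi)
estimator

    Var F₁(t) = Σ [F₁(t)−F₁(tᵢ)]² dᵢ/(nᵢ(nᵢ−dᵢ))
              + Σ S(tᵢ₋₁)² (nᵢ−d₁ᵢ)/nᵢ · d₁ᵢ/nᵢ²
              − 2 Σ [F₁(t)−F₁(tᵢ)] S(tᵢ₋₁) d₁ᵢ/nᵢ²,

skipping Greenwood terms where nᵢ = dᵢ. This differs from the Aalen-type
variance used by some reference software by ~1% in typical samples; both
are standard. 95% limits use the log(−log) transform,
F^{exp(±z·se/(F|log F|))}, which keeps bounds inside [0, 1]. On
censoring-free data F₁ + F₂ + S ≡ 1 at every event time (a tested
invariant), and with a single cause the estimator collapses to 1 − KM.

## Gray-type K-sample test

Differences in the cause-1 CIF across K groups are tested with the score
test of the IPCW subdistribution partial likelihood evaluated at β = 0 with
K−1 group indicators:

    U = Σ_j w(t_j) (s_j − d_j x̄(t_j)),    X² = U' V⁻¹ U,  df = K−1,

where x̄ and the covariance V are computed over the subdistribution risk
set (see Fine–Gray below) and w(t) = (1 − F̂₁(t⁻))^ρ with ρ = 0 by default.
Without censoring and without competing events the subdistribution risk set
is the ordinary risk set and the statistic *is* the (Breslow-tie) log-rank
chi-square — a tested identity. This regression-score formulation is
asymptotically equivalent to Gray's original K-sample statistic but not
numerically identical in finite samples; its null calibration is verified
by simulation in the test suite (uniform p-values over 500 null replicates
at n = 200, with censoring and competing deaths present).

## Fine–Gray regression

The subdistribution hazard model λ₁(t|x) = λ₁₀(t) exp(x'β) is fitted by
maximizing the weighted partial likelihood in which a subject who failed
from the competing cause at Tᵢ remains in the risk set at later event times
t with weight Ĝ(t⁻)/Ĝ(Tᵢ⁻), Ĝ being the Kaplan–Meier estimator of the
censoring distribution on the pooled sample (censorings as events, with the
reversed tie convention; group-stratified weights are available as an
option). Ties among cause-1 events are handled à la Breslow.

Numerics: Newton–Raphson from β = 0 with step-halving whenever the
log-likelihood decreases beyond numerical noise; convergence when the
max-norm of the score falls below 1e-9 × max(1, number of cause-1 events) —
the score is a sum over events, so its floating-point noise floor scales
with the event count, and an unscaled 1e-9 criterion stalls on cohorts of a
few thousand. Maximum 100 iterations; a coefficient excursion beyond 15 in
absolute value is flagged as separation, and non-convergence is reported in
the result object, never silently.

Variance is the robust sandwich H⁻¹(Σᵢ UᵢUᵢ')H⁻¹ over per-subject score
residuals by default (model-based H⁻¹ available). The sandwich treats the
censoring weights as known; the extra variance term from estimating Ĝ is
omitted. On a censored competing-risks fixture the coefficients agree with
the R reference implementation to 1e-7 and the SEs to within 1%, and the
empirical coverage of the 95% CI is 95% over 200 simulated cohorts of
n = 2000 — the omission is immaterial at the sample sizes this package
targets. p-values are two-sided Wald.

Without competing events and without censoring all weights are 1 and the
fit coincides with Cox partial likelihood (tested to 1e-6 against an
independent implementation).

## Time-dependent AUROC

Cumulative-cases / dynamic-controls definition at horizon τ: cases are
subjects with a cause-1 event in (0, τ]; controls are subjects event-free
beyond τ; subjects dying (competing event) by τ are kept as non-cases by
default — the definition consistent with 1 − CIF₁ as the control
probability — with an option to exclude them. IPCW weights from the pooled
censoring KM: 1/Ĝ(Tᵢ⁻) for cases and competing deaths, 1/Ĝ(τ) for
event-free controls. The AUC is the weighted probability that a random case
outranks a random control, ties counting ½; it is computed by weighted
ranking (no quadratic pair loop) and is invariant under strictly increasing
marker transforms. The variance is the two-sample weighted U-statistic
projection with weights treated as known; the 95% CI is Wald, clipped to
[0, 1]. A horizon with no cases or no controls (including horizons beyond
the last observed time) yields a flagged undefined result rather than a
number. The ROC curve sweeps the distinct marker values; its trapezoidal
area equals the AUC estimate exactly, ties included.

## Synthetic cohorts

The generator emulates the structure of a ~425-patient multicenter
validation cohort:

- **Covariates** are drawn independently from configurable marginals
  (defaults: the published frequencies — metastatic 68.0%, compression
  8.9%, prior VTE 7.3%, thrombocytosis 19.3%, leukocytosis 9.6%,
  anemia/ESA 5.6%, BMI ≥ 35 4.0%, and the 19-site tumor distribution).
  Continuous labs are back-filled consistently with the drawn indicator, so
  re-deriving components from the emitted values reproduces the draw. The
  Khorana > 2 flag is *computed* from the sampled components, never sampled.
- **Outcomes, stratum-target mode (default):** within each ONKOTEV stratum,
  latent VTE times are exponential with the rate solved (Brent) so that the
  true 6-month CIF of VTE under the competing death hazard equals the
  configured target exactly; defaults are the round values 2/8/20/30%
  across strata 0/1/2/>2 — deliberately round numbers, not estimates from
  any particular study. Death times are exponential (default 0.015/month,
  chosen to give roughly one death-first per 70 person-months as seen in
  cohorts of this kind); censoring is uniform on [8, 24] months with a 25%
  administrative fraction at 24. The first of the three latent times wins.
- **Outcomes, covariate-driven mode:** with `fine_gray_beta` set, VTE
  follows the improper subdistribution model
  P(VTE ever | x) = 1 − (1 − p₀)^{exp(x'β)} over the four ONKOTEV
  components (baseline p₀ = 0.10, exponential time transform), so the true
  subdistribution HR of component j is exp(β_j) exactly. Subjects not
  destined for VTE draw an exponential death time. This mode provides the
  ground truth for the parameter-recovery and coverage tests.

Everything is deterministic under the config seed, down to byte-identical
emitted CSVs.

What the generator does **not** emulate: covariate correlations (components
are independent given the configured marginals), center heterogeneity,
treatment effects, non-proportional subdistribution hazards, and any
particular real cohort's censoring pattern (the uniform-[8, 24] model is an
artifact assumption). Passing tests therefore demonstrate the correctness
and calibration of the estimators under the stated generative assumptions —
not the clinical performance of the scores on real patients.

## Validation pipeline

`run_validation` chains: cohort summary → scores and strata → first-event
counts → incidence per 100 person-months → per-stratum CIF with the 6-month
landmark → Gray-type test over non-empty strata (a single-stratum cohort
produces a note, not a crash) → four-covariate Fine–Gray model →
time-dependent AUROC at 3/6/12 months on the integer score → EPV check
(minimum n = ⌈EPV·k/incidence⌉ in exact rational arithmetic, so 10·4/0.10
yields 400 rather than a float-round-off 401). Percentages print with one
decimal, HRs and AUCs with two. No multiplicity correction is applied (one
global test plus per-covariate Wald p-values, reported in full); the 0.05
significance convention is echoed in the report settings but never used to
hide rows. Reports are deterministic given cohort and config and serialize
to delimited tables plus one JSON summary; step-curve coordinates are
emitted for plotting by the user.

## Problem sizes used in the automated checks

Oracle-equivalence checks run on enumerated cohorts of n ≤ 6 and fixtures
of n = 60–300. Parameter recovery uses 200 cohorts of n = 2000; Gray-test
null calibration uses 500 replicates of n = 200; the stratum CIF
convergence check uses one cohort of n = 20 000. These sizes give
Monte-Carlo error small enough for 3-SE assertions while keeping the whole
suite under a couple of minutes on one CPU.

## Known limitations

- Gray's test is the regression-score variant (see above), so its statistic
  differs in finite samples from the classical implementation, typically in
  the first decimal at n ≈ 150.
- The Fine–Gray and AUC variances ignore the censoring-weight estimation
  term (empirically negligible here; see coverage results).
- No time-varying covariates, left truncation, or more than two competing
  causes.
- Follow-up times are stored as given; no administrative truncation is
  applied at read time.
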