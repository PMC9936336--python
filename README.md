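# catrisk

Competing-risks validation toolkit for cancer-associated venous
thromboembolism (VTE) risk scores.

Ambulatory cancer patients starting systemic therapy face a substantial risk
of VTE, and risk assessment models (RAMs) are used to decide who should
receive primary thromboprophylaxis. `catrisk` implements two such scores and
the full statistical machinery needed to validate them on a cohort in which
death competes with VTE as a first event:

- **Khorana score** (0–6): 2 points for a very-high-risk tumor site
  (gastric, pancreas), 1 for a high-risk site (lung, lymphoma, gynecologic,
  bladder, testicular), and 1 each for hemoglobin < 10 g/dL or use of
  red-blood-cell growth factors, pre-chemotherapy leukocytes > 11 000/µL,
  pre-chemotherapy platelets ≥ 350 × 10³/µL, and BMI ≥ 35.
- **ONKOTEV score** (0–4): one point each for Khorana > 2, metastatic
  disease, macroscopic vascular/lymphatic compression, and prior VTE;
  analysed in four strata (0, 1, 2, >2).

The validation stack treats death before VTE as a competing event
throughout:

- **Cumulative incidence function** (Aalen–Johansen / Kalbfleisch–Prentice
  product-limit form) `F₁(t) = Σ_{tᵢ≤t} S(tᵢ⁻) d₁(tᵢ)/n(tᵢ)`, with
  delta-method pointwise variance and log(−log) 95% limits.
- **Gray-type K-sample test** for equality of CIFs across score strata,
  implemented as the score test of the IPCW subdistribution partial
  likelihood (it reduces exactly to the log-rank test without censoring or
  competing events).
- **Fine–Gray regression** of the subdistribution hazard
  `λ₁(t|x) = λ₁₀(t) exp(x'β)`: subjects failing from the competing cause
  remain in later risk sets with Kaplan–Meier censoring weights
  `G(t)/G(Tᵢ)`; Newton–Raphson fit, robust (sandwich) variance.
- **Time-dependent AUROC** (cumulative cases / dynamic controls, IPCW) at
  landmark horizons, with competing deaths kept as non-cases by default.
- **Events-per-variable planning**: minimum n = ⌈EPV·k / incidence⌉.

Because studies of this kind rarely deposit patient-level data, the package
ships a synthetic cohort generator (`catrisk.synthetic_data`) that emulates
the validation setting: published covariate marginals, a VTE risk gradient
across the four score strata, a competing death hazard, and 8–24 months of
follow-up. Its covariate-driven mode generates outcomes from an improper
subdistribution model with a known true subdistribution hazard ratio, which
the test suite uses for parameter-recovery and CI-calibration checks.

## Worked example

```bash
catrisk simulate --out demo.csv --seed 7 --n 425
catrisk validate demo.csv --out demo_report/
```

`demo_report/report.json` then contains (abridged; your numbers are
identical for the same seed):

```
events        {censored: 261, death_first: 71, vte_first: 93}
rate_per_100pm 1.6
cif_landmark  stratum 0   n=100  6-mo CIF 0.040 (0.013–0.092)
              stratum 1   n=268  6-mo CIF 0.090 (0.059–0.127)
              stratum 2   n=50   6-mo CIF 0.180 (0.089–0.297)
              stratum >2  n=7    6-mo CIF 0.143 (0.007–0.465)
gray          statistic 38.05, df 3, p 2.8e-08
fine_gray     khorana_gt2 HR 1.76 (0.95–3.25) p 0.073
              metastatic  HR 3.54 (1.94–6.48) p 4e-05
              compression HR 2.71 (1.63–4.49) p 1.2e-04
              prior_vte   HR 1.98 (1.02–3.86) p 0.044
auc           3 mo 0.63, 6 mo 0.62, 12 mo 0.64
power         required_n 400, cohort_n 425, adequate true
```

Reading it: of 425 simulated patients, 93 had VTE as first event and 71 died
first (competing events); VTE incidence was 1.6 per 100 person-months. The
6-month cumulative incidence of VTE rises across the score strata and the
Gray-type test rejects equality (p < 10⁻⁷). The Fine–Gray model attributes
the gradient mostly to metastatic disease and compression in this draw, and
the score's discrimination (AUROC ≈ 0.62–0.64) is moderate — as expected for
a 5-level ordinal marker. The cohort exceeds the 400-patient minimum implied
by 10 events per predictor at 10% expected incidence.

The same analyses are available as library calls: `read_cohort`,
`eligibility_filter`, `complete_case_filter`, `score_cohort`,
`estimate_cif`/`cif_at`, `gray_test`, `fine_gray_fit`, `td_auc`,
`run_validation`. See `docs/methods.md` for the statistical details and
design choices.

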