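"""Synthetic cohort generator for exercising the validation pipeline.

No patient-level data accompany the validation study, so this module
generates cohorts with the statistical structure the analysis assumes:
covariates drawn independently from the published marginal frequencies of a
~425-patient multicenter cohort, a VTE hazard that rises across the four
ONKOTEV strata (parameterised directly by per-stratum 6-month cumulative
incidence targets), death as a competing first event with a constant
hazard, and censoring between 8 and 24 months of follow-up.

Two outcome engines are available:

* stratum-target mode (default): within each ONKOTEV stratum, latent VTE
  times are exponential with the rate solved so that the true 6-month CIF of
  VTE -- accounting for the competing death hazard -- equals the configured
  target exactly.
* covariate-driven mode (``fine_gray_beta`` set): outcomes follow the
  improper subdistribution model P(VTE ever | x) = 1 - (1 - p0)^exp(x'beta)
  over the four ONKOTEV component flags, so the true subdistribution hazard
  ratio of component j is exactly exp(beta_j) -- the ground truth used for
  Fine-Gray parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import scoring
from .cohort_io import SCHEMA_COLUMNS, Cohort

__all__ = [
    "CensoringConfig",
    "SimulationConfig",
    "DEFAULT_SITE_FREQUENCIES",
    "DEFAULT_MARGINALS",
    "sample_covariates",
    "simulate_outcomes",
    "simulate_cohort",
]

#: Tumor-site frequencies (counts in the 425-patient reference cohort).
DEFAULT_SITE_FREQUENCIES: dict[str, int] = {
    "colon": 54,
    "rectum": 46,
    "breast": 77,
    "gastric": 70,
    "lung": 47,
    "pancreas": 32,
    "biliary_tract": 13,
    "bladder_urinary": 3,
    "prostate": 1,
    "mesothelioma": 2,
    "head_neck": 7,
    "gynecologic_urological": 26,
    "anus": 4,
    "sarcoma": 2,
    "esophagus": 7,
    "skin": 2,
    "neuroendocrine": 24,
    "appendix": 1,
    "unknown": 7,
}

#: Marginal frequencies of the binary covariates (reference cohort rates).
DEFAULT_MARGINALS: dict[str, float] = {
    "female": 242 / 425,
    "anemia_or_esa": 24 / 425,
    "leukocytosis": 41 / 425,
    "thrombocytosis": 82 / 425,
    "obesity": 17 / 425,
    "metastatic": 289 / 425,
    "compression": 38 / 425,
    "prior_vte": 31 / 425,
}

#: Round per-stratum 6-month VTE CIF targets, rising across strata.
DEFAULT_CIF6_TARGETS: dict[str, float] = {"0": 0.02, "1": 0.08, "2": 0.20, ">2": 0.30}

#: Order of the covariates that ``fine_gray_beta`` refers to.
FINE_GRAY_COVARIATES = ("khorana_gt2", "metastatic", "compression", "prior_vte")


@dataclass(frozen=True)
class CensoringConfig:
    """Censoring model: a fraction censored administratively at the maximum
    follow-up, the remainder uniform on [min, max] months."""

    min_followup_months: float = 8.0
    max_followup_months: float = 24.0
    administrative_fraction: float = 0.25

    def __post_init__(self):
        if not 0 <= self.administrative_fraction <= 1:
            raise ValueError("administrative_fraction must be in [0, 1]")
        if not 0 < self.min_followup_months < self.max_followup_months:
            raise ValueError("need 0 < min_followup < max_followup")


@dataclass(frozen=True)
class SimulationConfig:
    n: int = 425
    seed: int = 0
    site_frequencies: dict = field(default_factory=lambda: dict(DEFAULT_SITE_FREQUENCIES))
    covariate_marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    score_level_cif6: dict = field(default_factory=lambda: dict(DEFAULT_CIF6_TARGETS))
    death_rate: float = 0.015  # per month; ~16% dead first within ~1 year
    censoring: CensoringConfig = field(default_factory=CensoringConfig)
    fine_gray_beta: tuple | None = None
    fine_gray_p0: float = 0.10
    fine_gray_rate: float = 1.0 / 6.0  # per month, baseline VTE time scale

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name, p in self.covariate_marginals.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"marginal frequency for {name!r} must be in [0, 1]")
        for stratum, p in self.score_level_cif6.items():
            if not 0.0 <= p < 1.0:
                raise ValueError(f"6-month CIF target for stratum {stratum!r} must be in [0, 1)")
        if any(c < 0 for c in self.site_frequencies.values()) or sum(self.site_frequencies.values()) <= 0:
            raise ValueError("site frequencies must be non-negative and not all zero")
        if self.death_rate < 0:
            raise ValueError("death_rate must be >= 0")
        if not 0.0 < self.fine_gray_p0 < 1.0:
            raise ValueError("fine_gray_p0 must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "censoring" in d and isinstance(d["censoring"], dict):
            d["censoring"] = CensoringConfig(**d["censoring"])
        if d.get("fine_gray_beta") is not None:
            d["fine_gray_beta"] = tuple(float(b) for b in d["fine_gray_beta"])
        return cls(**d)


def sample_covariates(config: SimulationConfig) -> Cohort:
    """Draw baseline covariates for ``config.n`` patients (outcomes unset).

    Binary risk indicators are drawn at their configured marginal rates and
    the continuous labs are back-filled consistently with the indicator
    (e.g. a thrombocytosis-positive subject receives a platelet count at or
    above 350 x 10^3/uL), so re-deriving the components from the emitted
    values reproduces the drawn indicators.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    m = config.covariate_marginals

    sites = list(config.site_frequencies)
    probs = np.array([config.site_frequencies[s] for s in sites], dtype=float)
    probs /= probs.sum()
    tumor_site = rng.choice(sites, size=n, p=probs)

    female = rng.random(n) < m["female"]
    age = np.clip(np.round(rng.normal(61.0, 12.0, n)), 20, 92)

    anemia = rng.random(n) < m["anemia_or_esa"]
    esa = np.zeros(n, dtype=bool)
    hgb = np.round(rng.uniform(10.2, 15.5, n), 1)
    esa_among_anemia = rng.random(n) < 0.3
    low_hgb = anemia & ~esa_among_anemia
    hgb[low_hgb] = np.round(rng.uniform(8.0, 9.9, int(low_hgb.sum())), 1)
    esa[anemia & esa_among_anemia] = True

    leuko_flag = rng.random(n) < m["leukocytosis"]
    leuko = np.round(rng.uniform(4000, 10_900, n), 0)
    leuko[leuko_flag] = np.round(rng.uniform(11_100, 25_000, int(leuko_flag.sum())), 0)

    plate_flag = rng.random(n) < m["thrombocytosis"]
    plate = np.round(rng.uniform(150_000, 349_000, n), 0)
    plate[plate_flag] = np.round(rng.uniform(350_000, 700_000, int(plate_flag.sum())), 0)

    obese = rng.random(n) < m["obesity"]
    bmi = np.round(np.clip(rng.normal(24.4, 4.0, n), 15.1, 34.9), 1)
    bmi[obese] = np.round(rng.uniform(35.0, 44.8, int(obese.sum())), 1)

    metastatic = rng.random(n) < m["metastatic"]
    compression = rng.random(n) < m["compression"]
    prior_vte = rng.random(n) < m["prior_vte"]

    data = pd.DataFrame(
        {
            "patient_id": [f"SIM-{i + 1:05d}" for i in range(n)],
            "age_years": age.astype(float),
            "sex": pd.array(np.where(female, "female", "male"), dtype="string"),
            "bmi": bmi,
            "tumor_site": pd.array(tumor_site, dtype="string"),
            "site_risk_override": pd.array([None] * n, dtype="string"),
            "hemoglobin_g_dl": hgb,
            "uses_rbc_growth_factors": pd.array(esa, dtype="boolean"),
            "leukocytes_per_ul": leuko,
            "platelets_per_ul": plate,
            "metastatic": pd.array(metastatic, dtype="boolean"),
            "vascular_lymphatic_compression": pd.array(compression, dtype="boolean"),
            "prior_vte": pd.array(prior_vte, dtype="boolean"),
            "on_anticoagulation": pd.array(np.zeros(n, dtype=bool), dtype="boolean"),
            "time_months": np.full(n, np.nan),
            "event": np.full(n, np.nan),
        }
    )[list(SCHEMA_COLUMNS)]
    return Cohort(data=data, provenance=f"synthetic(seed={config.seed}, n={n})")


def _solve_cause1_rate(target_cif6: float, death_rate: float) -> float:
    """Rate of the latent exponential VTE time such that the true 6-month
    CIF of VTE under an independent Exp(death_rate) competing death equals
    ``target_cif6``:  F1(6) = l1/(l1+ld) * (1 - exp(-6(l1+ld)))."""
    if target_cif6 == 0.0:
        return 0.0

    def f(l1):
        tot = l1 + death_rate
        return l1 / tot * -np.expm1(-6.0 * tot) - target_cif6

    return float(brentq(f, 1e-12, 1e3, xtol=1e-14, rtol=1e-14))


def _draw_censoring(rng, n: int, cfg: CensoringConfig) -> np.ndarray:
    c = rng.uniform(cfg.min_followup_months, cfg.max_followup_months, n)
    admin = rng.random(n) < cfg.administrative_fraction
    c[admin] = cfg.max_followup_months
    return c


def simulate_outcomes(cohort: Cohort, config: SimulationConfig) -> Cohort:
    """Fill ``time_months`` and ``event`` for a covariate-only cohort.

    The first of (latent VTE time, latent death time, censoring time) wins;
    event is coded 1 / 2 / 0 respectively.  Deterministic for a fixed
    config seed.
    """
    scored = scoring.score_cohort(cohort.data)
    if scored["onkotev_stratum"].isna().any():
        raise ValueError("cannot simulate outcomes: some records have incomputable scores")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(scored)

    if config.fine_gray_beta is not None:
        beta = np.asarray(config.fine_gray_beta, dtype=float)
        Z = np.column_stack(
            [np.asarray(scored[_fg_column(c)], dtype=float) for c in FINE_GRAY_COVARIATES[: len(beta)]]
        )
        eta = Z @ beta
        p0, lam = config.fine_gray_p0, config.fine_gray_rate
        pi = -np.expm1(np.exp(eta) * np.log1p(-p0))  # 1 - (1-p0)^exp(eta)
        v = rng.random(n)
        is_vte = v < pi
        # invert F1(t | x) = v on the VTE-destined branch
        inner = (1.0 - np.exp(np.exp(-eta) * np.log1p(-v))) / p0
        inner = np.clip(inner, 0.0, 1.0 - 1e-15)
        t_vte = -np.log1p(-inner) / lam
        t_death = (
            rng.exponential(1.0 / config.death_rate, n) if config.death_rate > 0 else np.full(n, np.inf)
        )
        latent_t = np.where(is_vte, t_vte, t_death)
        latent_e = np.where(is_vte, 1, np.where(np.isfinite(latent_t), 2, 0))
    else:
        strata = np.asarray(scored["onkotev_stratum"].astype(str))
        rates = {s: _solve_cause1_rate(config.score_level_cif6[s], config.death_rate) for s in config.score_level_cif6}
        lam1 = np.array([rates[s] for s in strata])
        with np.errstate(divide="ignore"):
            t_vte = rng.exponential(1.0, n) / np.where(lam1 > 0, lam1, np.nan)
        t_vte = np.where(lam1 > 0, t_vte, np.inf)
        t_death = (
            rng.exponential(1.0 / config.death_rate, n) if config.death_rate > 0 else np.full(n, np.inf)
        )
        latent_t = np.minimum(t_vte, t_death)
        latent_e = np.where(t_vte <= t_death, 1, 2)
        latent_e = np.where(np.isfinite(latent_t), latent_e, 0)

    c = _draw_censoring(rng, n, config.censoring)
    time = np.minimum(latent_t, c)
    event = np.where(latent_t <= c, latent_e, 0)
    time = np.round(np.maximum(time, 1e-3), 4)

    data = cohort.data.copy()
    data["time_months"] = time
    data["event"] = event.astype(float)
    return Cohort(
        data=data,
        provenance=cohort.provenance,
        filter_log=list(cohort.filter_log),
        parse_report=dict(cohort.parse_report),
    )


def _fg_column(component: str) -> str:
    return "vascular_lymphatic_compression" if component == "compression" else component


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Covariates plus outcomes in one call."""
    return simulate_outcomes(sample_covariates(config), config)
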