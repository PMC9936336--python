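"""End-to-end validation of a risk score on a competing-risks cohort.

``run_validation`` chains the whole analysis the way a score-validation
study reports it: cohort summary, score distribution, first-event counts,
incidence rate per 100 person-months, cumulative incidence of VTE by score
stratum (with the 6-month landmark), Gray-type test across strata,
multivariable Fine-Gray regression on the four score components,
time-dependent AUROC at 3/6/12 months, and an events-per-variable
sample-size check.  The report is a plain dataclass serializable to a
directory of delimited tables plus one machine-readable JSON summary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_io, competing_risks, discrimination, scoring
from .cohort_io import Cohort
from .competing_risks import (
    FineGrayFit,
    GrayTestResult,
    SurvivalData,
    cif_at,
    estimate_cif,
    fine_gray_fit,
    gray_test,
    incidence_rate,
)
from .discrimination import TimeDependentAUC, td_auc

__all__ = ["ValidationConfig", "ValidationReport", "epv_sample_size", "run_validation", "write_report"]

FINE_GRAY_COLUMNS = {
    "khorana_gt2": "khorana_gt2",
    "metastatic": "metastatic",
    "compression": "vascular_lymphatic_compression",
    "prior_vte": "prior_vte",
}


def epv_sample_size(events_per_variable: int, n_predictors: int, expected_incidence: float) -> int:
    """Minimum cohort size under the events-per-variable rule of thumb.

    ceil(events_per_variable * n_predictors / expected_incidence), computed
    in exact rational arithmetic so boundary cases are not corrupted by
    floating-point round-off.
    """
    if events_per_variable <= 0 or n_predictors <= 0:
        raise ValueError("events_per_variable and n_predictors must be > 0")
    if not 0.0 < expected_incidence < 1.0:
        raise ValueError("expected_incidence must be in (0, 1)")
    exact = Fraction(events_per_variable * n_predictors) / Fraction(expected_incidence)
    return int(math.ceil(exact))


@dataclass(frozen=True)
class ValidationConfig:
    cif_landmark_months: float = 6.0
    auc_horizons_months: tuple = (3.0, 6.0, 12.0)
    epv_events_per_variable: int = 10
    epv_expected_incidence: float = 0.10
    fine_gray_variance: str = "robust"
    significance_level: float = 0.05


@dataclass
class ValidationReport:
    n: int
    cohort_summary: pd.DataFrame
    score_distribution: pd.DataFrame
    events: dict
    person_time_months: float
    rate_per_100pm: float
    cif_by_stratum: dict
    cif_landmark: pd.DataFrame
    gray: GrayTestResult | None
    gray_note: str
    fine_gray: FineGrayFit
    auc: list
    power: dict
    notes: list = field(default_factory=list)
    settings: dict = field(default_factory=dict)


def run_validation(cohort: Cohort, config: ValidationConfig = ValidationConfig()) -> ValidationReport:
    """Run the full score-validation analysis on a filtered cohort.

    The cohort must already have passed the eligibility and complete-case
    filters (every record needs a computable ONKOTEV score and outcome).
    Deterministic given cohort and config.
    """
    scored = scoring.score_cohort(cohort.data)
    if scored["onkotev_stratum"].isna().any() or scored[["time_months", "event"]].isna().any().any():
        raise ValueError("run_validation requires a complete-case cohort (apply the filters first)")
    n = len(scored)
    notes: list[str] = []

    summary = cohort_io.summarize_cohort(cohort)

    dist_rows = []
    for s in range(5):
        cnt = int((scored["onkotev_score"] == s).sum())
        dist_rows.append(("score", str(s), cnt))
    for label in scoring.ONKOTEV_STRATA:
        dist_rows.append(("stratum", label, int((scored["onkotev_stratum"] == label).sum())))
    score_distribution = pd.DataFrame(dist_rows, columns=["kind", "level", "count"])

    event = np.asarray(scored["event"], dtype=float).astype(int)
    events = {
        "vte_first": int((event == 1).sum()),
        "death_first": int((event == 2).sum()),
        "censored": int((event == 0).sum()),
    }
    person_time = float(np.asarray(scored["time_months"], dtype=float).sum())
    rate = incidence_rate(events["vte_first"], person_time)

    sdata = SurvivalData.from_cohort(scored, group="onkotev_stratum")

    strata_present = [s for s in scoring.ONKOTEV_STRATA if (scored["onkotev_stratum"] == s).any()]
    empty = [s for s in scoring.ONKOTEV_STRATA if s not in strata_present]
    if empty:
        notes.append(f"strata with zero subjects omitted from CIF/Gray: {', '.join(empty)}")

    cif_by_stratum = estimate_cif(sdata, cause=1)
    landmark_rows = []
    for s in strata_present:
        est = cif_by_stratum[s]
        point, lo, hi = cif_at(est, config.cif_landmark_months)
        mask = scored["onkotev_stratum"] == s
        landmark_rows.append(
            {
                "stratum": s,
                "n": int(mask.sum()),
                "n_vte": int((scored.loc[mask, "event"] == 1).sum()),
                "cif": point,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    cif_landmark = pd.DataFrame(landmark_rows)

    if len(strata_present) >= 2:
        gray = gray_test(sdata, cause=1)
        gray_note = ""
    else:
        gray = None
        gray_note = "single stratum: Gray test not applicable"
        notes.append(gray_note)

    fg_data = scored.copy()
    for name, col in FINE_GRAY_COLUMNS.items():
        fg_data[name] = np.asarray(fg_data[col], dtype=float)
    fg = fine_gray_fit(
        SurvivalData.from_cohort(fg_data, covariates=list(FINE_GRAY_COLUMNS)),
        cause=1,
        variance=config.fine_gray_variance,
    )
    if not fg.converged:
        notes.append("Fine-Gray fit did not converge; interpret with caution")

    marker = np.asarray(scored["onkotev_score"], dtype=float)
    aucs = [td_auc(sdata, marker, h) for h in config.auc_horizons_months]
    for a in aucs:
        if not a.defined:
            notes.append(f"AUROC undefined at {a.horizon_months:g} months (no cases or no controls)")

    required_n = epv_sample_size(config.epv_events_per_variable, len(FINE_GRAY_COLUMNS), config.epv_expected_incidence)
    power = {
        "events_per_variable": config.epv_events_per_variable,
        "n_predictors": len(FINE_GRAY_COLUMNS),
        "expected_incidence": config.epv_expected_incidence,
        "required_n": required_n,
        "cohort_n": n,
        "adequate": n >= required_n,
    }

    settings = {
        "cif_landmark_months": config.cif_landmark_months,
        "auc_horizons_months": list(config.auc_horizons_months),
        "fine_gray_variance": config.fine_gray_variance,
        "significance_level": config.significance_level,
        "multiple_testing_correction": "none",
        "filters": [(e.name, e.n_removed, e.reason) for e in cohort.filter_log],
        "provenance": cohort.provenance,
    }
    return ValidationReport(
        n=n,
        cohort_summary=summary,
        score_distribution=score_distribution,
        events=events,
        person_time_months=person_time,
        rate_per_100pm=rate,
        cif_by_stratum=cif_by_stratum,
        cif_landmark=cif_landmark,
        gray=gray,
        gray_note=gray_note,
        fine_gray=fg,
        auc=aucs,
        power=power,
        notes=notes,
        settings=settings,
    )


def _auc_table(aucs: list[TimeDependentAUC]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "horizon_months": [a.horizon_months for a in aucs],
            "auc": [round(a.auc, 4) if a.defined else float("nan") for a in aucs],
            "ci_low": [round(a.ci_low, 4) if a.defined else float("nan") for a in aucs],
            "ci_high": [round(a.ci_high, 4) if a.defined else float("nan") for a in aucs],
            "n_cases": [a.n_cases for a in aucs],
            "n_controls": [a.n_controls for a in aucs],
        }
    )


def write_report(report: ValidationReport, out_dir) -> None:
    """Serialize a report to ``out_dir``: delimited tables plus report.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.cohort_summary.to_csv(out / "cohort_summary.csv", index=False, lineterminator="\n")
    report.score_distribution.to_csv(out / "score_distribution.csv", index=False, lineterminator="\n")
    report.cif_landmark.to_csv(out / "cif_landmark.csv", index=False, lineterminator="\n")
    report.fine_gray.summary().to_csv(out / "fine_gray.csv", index=False, lineterminator="\n")
    _auc_table(report.auc).to_csv(out / "auc.csv", index=False, lineterminator="\n")

    curves = []
    for s, est in report.cif_by_stratum.items():
        for t, c, lo, hi in zip(est.times, est.cif, est.ci_low, est.ci_high):
            curves.append({"stratum": s, "time_months": t, "cif": c, "ci_low": lo, "ci_high": hi})
    pd.DataFrame(curves).to_csv(out / "cif_curves.csv", index=False, lineterminator="\n")

    payload = {
        "n": report.n,
        "events": report.events,
        "person_time_months": round(report.person_time_months, 4),
        "rate_per_100pm": round(report.rate_per_100pm, 1),
        "cif_landmark": report.cif_landmark.round(6).to_dict(orient="records"),
        "gray": (
            {"statistic": report.gray.statistic, "df": report.gray.df, "p_value": report.gray.p_value}
            if report.gray is not None
            else {"note": report.gray_note}
        ),
        "fine_gray": {
            "converged": report.fine_gray.converged,
            "n_events": report.fine_gray.n_events,
            "n_competing": report.fine_gray.n_competing,
            "rows": report.fine_gray.summary().round(6).to_dict(orient="records"),
        },
        "auc": _auc_table(report.auc).to_dict(orient="records"),
        "power": report.power,
        "notes": report.notes,
        "settings": report.settings,
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True, allow_nan=True) + "\n")
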