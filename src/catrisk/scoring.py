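"""Khorana and ONKOTEV risk scores for cancer-associated venous thromboembolism.

The Khorana score is an additive pre-chemotherapy risk score built from five
components: tumor-site risk category (very-high-risk sites score 2, high-risk
sites 1), anemia or use of red-blood-cell growth factors, leukocytosis,
thrombocytosis, and obesity.  The ONKOTEV score counts four binary factors --
a Khorana score above 2, metastatic disease, macroscopic vascular or lymphatic
compression, and a personal history of VTE -- and is analysed in four strata
(0, 1, 2, >2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "KhoranaComponents",
    "OnkotevComponents",
    "ScoreResult",
    "ScoreConfig",
    "DEFAULT_SITE_RISK",
    "ONKOTEV_STRATA",
    "site_risk_category",
    "khorana_score",
    "onkotev_score",
    "onkotev_stratum",
    "score_cohort",
]

SITE_RISK_LEVELS = ("low", "high", "very_high")

#: Default tumor-site -> Khorana risk category mapping.  Very-high-risk sites
#: are gastric/gastroesophageal and pancreatic primaries; high-risk sites are
#: lung, lymphoma, gynecologic, bladder/urinary and testicular; every other
#: site (including unknown primary) is low risk.
DEFAULT_SITE_RISK: dict[str, str] = {
    "gastric": "very_high",
    "stomach": "very_high",
    "gastroesophageal": "very_high",
    "pancreas": "very_high",
    "lung": "high",
    "lymphoma": "high",
    "gynecologic": "high",
    "gynecologic_urological": "high",
    "bladder": "high",
    "bladder_urinary": "high",
    "testicular": "high",
    # explicit low-risk entries for the sites the cohort schema enumerates
    "colon": "low",
    "rectum": "low",
    "breast": "low",
    "biliary_tract": "low",
    "prostate": "low",
    "mesothelioma": "low",
    "head_neck": "low",
    "anus": "low",
    "sarcoma": "low",
    "esophagus": "low",
    "skin": "low",
    "neuroendocrine": "low",
    "appendix": "low",
    "unknown": "low",
}

#: Labels of the four validation strata, in order.
ONKOTEV_STRATA = ("0", "1", "2", ">2")

# Lab/anthropometric thresholds entering the Khorana components.
HEMOGLOBIN_THRESHOLD_G_DL = 10.0
LEUKOCYTE_THRESHOLD_PER_UL = 11_000.0
PLATELET_THRESHOLD_PER_UL = 350_000.0
BMI_THRESHOLD = 35.0


@dataclass(frozen=True)
class ScoreConfig:
    """User-editable scoring configuration.

    ``site_risk`` maps tumor-site labels to {low, high, very_high};
    ``khorana_weights`` holds the per-component point values.  The component
    thresholds themselves (Hgb < 10 g/dL, WBC > 11 000/uL, platelets >=
    350 x 10^3/uL, BMI >= 35) are fixed definitions, not configuration.
    """

    site_risk: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_SITE_RISK))
    khorana_weights: Mapping[str, int] = field(
        default_factory=lambda: {
            "site_very_high": 2,
            "site_high": 1,
            "anemia_or_esa": 1,
            "leukocytosis": 1,
            "thrombocytosis": 1,
            "obesity": 1,
        }
    )
    unknown_site_risk: str = "low"


DEFAULT_SCORE_CONFIG = ScoreConfig()


@dataclass(frozen=True)
class KhoranaComponents:
    """The five inputs of the Khorana score, fully resolved (no missing values)."""

    site_risk: str
    anemia_or_esa: bool
    leukocytosis: bool
    thrombocytosis: bool
    obesity: bool

    def __post_init__(self) -> None:
        if self.site_risk not in SITE_RISK_LEVELS:
            raise ValueError(f"site_risk must be one of {SITE_RISK_LEVELS}, got {self.site_risk!r}")
        for name in ("anemia_or_esa", "leukocytosis", "thrombocytosis", "obesity"):
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise ValueError(f"Khorana component {name!r} is missing")


@dataclass(frozen=True)
class OnkotevComponents:
    """The four binary factors of the ONKOTEV score."""

    khorana_gt2: bool
    metastatic: bool
    compression: bool
    prior_vte: bool

    def __post_init__(self) -> None:
        for name in ("khorana_gt2", "metastatic", "compression", "prior_vte"):
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise ValueError(f"ONKOTEV component {name!r} is missing")


@dataclass(frozen=True)
class ScoreResult:
    khorana: int
    onkotev: int
    stratum: str


def site_risk_category(tumor_site: str, config: ScoreConfig = DEFAULT_SCORE_CONFIG) -> str:
    """Map a tumor-site label to its Khorana risk category.

    Unknown labels fall back to ``config.unknown_site_risk`` (default low)
    with a warning, so a cohort with an unanticipated site label degrades
    gracefully rather than crashing.
    """
    key = str(tumor_site).strip().lower()
    try:
        return config.site_risk[key]
    except KeyError:
        warnings.warn(
            f"tumor site {tumor_site!r} not in the configured vocabulary; "
            f"treating as {config.unknown_site_risk}-risk",
            stacklevel=2,
        )
        return config.unknown_site_risk


def khorana_score(components: KhoranaComponents, config: ScoreConfig = DEFAULT_SCORE_CONFIG) -> int:
    """Compute the Khorana score (0..6) from its five components."""
    w = config.khorana_weights
    score = 0
    if components.site_risk == "very_high":
        score += w["site_very_high"]
    elif components.site_risk == "high":
        score += w["site_high"]
    score += w["anemia_or_esa"] * bool(components.anemia_or_esa)
    score += w["leukocytosis"] * bool(components.leukocytosis)
    score += w["thrombocytosis"] * bool(components.thrombocytosis)
    score += w["obesity"] * bool(components.obesity)
    return int(score)


def onkotev_stratum(onkotev: int) -> str:
    """Pool ONKOTEV scores into the four validation strata 0 / 1 / 2 / >2."""
    if onkotev < 0:
        raise ValueError("ONKOTEV score cannot be negative")
    return ONKOTEV_STRATA[min(onkotev, 3)]


def onkotev_score(components: OnkotevComponents, khorana: int | None = None) -> ScoreResult:
    """Sum the four ONKOTEV factors (one point each) and assign the stratum.

    ``khorana`` is reported in the result when supplied; otherwise the
    Khorana value in the result is -1 meaning "not carried through".
    """
    onkotev = int(
        bool(components.khorana_gt2)
        + bool(components.metastatic)
        + bool(components.compression)
        + bool(components.prior_vte)
    )
    return ScoreResult(
        khorana=-1 if khorana is None else int(khorana),
        onkotev=onkotev,
        stratum=onkotev_stratum(onkotev),
    )


def _anemia_component(hgb, esa):
    """OR-combine hemoglobin < 10 g/dL with ESA use under three-valued logic.

    Returns True/False/None; None means the component is undecidable from the
    available fields.
    """
    hgb_low = None if hgb is None or (isinstance(hgb, float) and np.isnan(hgb)) else hgb < HEMOGLOBIN_THRESHOLD_G_DL
    esa_flag = None if esa is None or (isinstance(esa, float) and np.isnan(esa)) else bool(esa)
    if hgb_low is True or esa_flag is True:
        return True
    if hgb_low is False and esa_flag is False:
        return False
    return None


def khorana_components_from_record(
    row: Mapping, config: ScoreConfig = DEFAULT_SCORE_CONFIG
) -> KhoranaComponents | None:
    """Resolve the Khorana components for one cohort record.

    Returns None when any component is undecidable (missing input); the
    complete-case filter excludes such records wholesale.
    An explicit ``site_risk_override`` takes precedence over the tumor-site
    lookup.
    """
    override = row.get("site_risk_override")
    if isinstance(override, str) and override.strip():
        site_risk = override.strip().lower()
        if site_risk not in SITE_RISK_LEVELS:
            raise ValueError(f"invalid site_risk_override {override!r}")
    else:
        site = row.get("tumor_site")
        if site is None or (isinstance(site, float) and np.isnan(site)) or str(site).strip() == "":
            return None
        site_risk = site_risk_category(site, config)

    anemia = _anemia_component(row.get("hemoglobin_g_dl"), row.get("uses_rbc_growth_factors"))

    def _bool_from(value, threshold):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        return bool(value >= threshold) if threshold is not None else bool(value)

    leuko = row.get("leukocytes_per_ul")
    leuko = None if leuko is None or (isinstance(leuko, float) and np.isnan(leuko)) else leuko > LEUKOCYTE_THRESHOLD_PER_UL
    plate = _bool_from(row.get("platelets_per_ul"), PLATELET_THRESHOLD_PER_UL)
    obesity = _bool_from(row.get("bmi"), BMI_THRESHOLD)

    if anemia is None or leuko is None or plate is None or obesity is None:
        return None
    return KhoranaComponents(
        site_risk=site_risk,
        anemia_or_esa=anemia,
        leukocytosis=leuko,
        thrombocytosis=plate,
        obesity=obesity,
    )


def score_cohort(data: pd.DataFrame, config: ScoreConfig = DEFAULT_SCORE_CONFIG) -> pd.DataFrame:
    """Append score columns to a cohort table.

    Adds ``khorana_score`` (nullable Int64; <NA> when undecidable),
    ``khorana_gt2``, ``onkotev_score`` and ``onkotev_stratum`` (both <NA> when
    any ONKOTEV input is missing).  The input frame is not modified.
    """
    out = data.copy()
    khorana = np.full(len(out), np.nan)
    for i, (_, row) in enumerate(out.iterrows()):
        comps = khorana_components_from_record(row, config)
        if comps is not None:
            khorana[i] = khorana_score(comps, config)
    out["khorana_score"] = pd.array(
        [int(k) if not np.isnan(k) else None for k in khorana], dtype="Int64"
    )
    gt2 = pd.array(
        [None if np.isnan(k) else bool(k > 2) for k in khorana], dtype="boolean"
    )
    out["khorana_gt2"] = gt2

    onkotev_vals: list[int | None] = []
    strata: list[str | None] = []
    for i, (_, row) in enumerate(out.iterrows()):
        flags = [gt2[i], row.get("metastatic"), row.get("vascular_lymphatic_compression"), row.get("prior_vte")]
        clean = []
        missing = False
        for f in flags:
            if f is None or f is pd.NA or (isinstance(f, float) and np.isnan(f)):
                missing = True
                break
            clean.append(bool(f))
        if missing:
            onkotev_vals.append(None)
            strata.append(None)
        else:
            total = sum(clean)
            onkotev_vals.append(total)
            strata.append(onkotev_stratum(total))
    out["onkotev_score"] = pd.array(onkotev_vals, dtype="Int64")
    out["onkotev_stratum"] = pd.array(strata, dtype="string")
    return out
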