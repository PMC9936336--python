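"""Read, validate, filter and summarize patient cohorts.

The on-disk format is UTF-8 delimited text (comma by default) with a fixed
header.  One row is one patient: demographics, tumor site, pre-treatment
labs, the ONKOTEV risk flags, and first-event follow-up (``time_months``,
``event`` with 0 = censored, 1 = VTE, 2 = death as first event).  Unparseable
cells become missing values and are counted in a parse report rather than
aborting the read; structural problems (missing mandatory columns, duplicate
patient ids) raise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import scoring

__all__ = [
    "SCHEMA_COLUMNS",
    "Cohort",
    "CohortSchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "complete_case_filter",
    "eligibility_filter",
    "summarize_cohort",
]

#: Fixed column order of the cohort schema.
SCHEMA_COLUMNS = (
    "patient_id",
    "age_years",
    "sex",
    "bmi",
    "tumor_site",
    "site_risk_override",
    "hemoglobin_g_dl",
    "uses_rbc_growth_factors",
    "leukocytes_per_ul",
    "platelets_per_ul",
    "metastatic",
    "vascular_lymphatic_compression",
    "prior_vte",
    "on_anticoagulation",
    "time_months",
    "event",
)

MANDATORY_COLUMNS = ("patient_id", "time_months", "event")

_NUMERIC_COLUMNS = ("age_years", "bmi", "hemoglobin_g_dl", "leukocytes_per_ul", "platelets_per_ul", "time_months")
_BOOL_COLUMNS = ("uses_rbc_growth_factors", "metastatic", "vascular_lymphatic_compression", "prior_vte", "on_anticoagulation")

# sanity bounds; values outside are rejected (set missing, counted in the parse report)
_BMI_BOUNDS = (10.0, 80.0)
_HGB_BOUNDS = (2.0, 25.0)

_TRUE_TOKENS = {"1", "true", "yes", "y", "t"}
_FALSE_TOKENS = {"0", "false", "no", "n", "f"}


class CohortSchemaError(ValueError):
    """The file header does not match the cohort schema."""


class CohortValidationError(ValueError):
    """Parsed records violate a cohort-level invariant."""


@dataclass(frozen=True)
class FilterLogEntry:
    name: str
    n_removed: int
    reason: str


@dataclass
class Cohort:
    """A parsed cohort: a record table plus provenance and a filter log.

    ``data`` holds one row per patient in schema order; ``filter_log``
    accumulates one entry per applied filter so that the exclusion flow of a
    study can be reconstructed from the object alone.
    """

    data: pd.DataFrame
    provenance: str = ""
    filter_log: list[FilterLogEntry] = field(default_factory=list)
    parse_report: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_removed(self) -> int:
        return sum(e.n_removed for e in self.filter_log)

    def _with_data(self, data: pd.DataFrame, entry: FilterLogEntry) -> "Cohort":
        return Cohort(
            data=data.reset_index(drop=True),
            provenance=self.provenance,
            filter_log=[*self.filter_log, entry],
            parse_report=dict(self.parse_report),
        )


def _parse_bool(token: str):
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    return None


def read_cohort(path, delimiter: str = ",", provenance: str | None = None) -> Cohort:
    """Parse a delimited-text cohort file.

    Empty strings are missing values.  A cell that fails to parse (or falls
    outside the BMI/hemoglobin sanity bounds) is set missing and counted in
    ``parse_report`` keyed by column name.  Raises :class:`CohortSchemaError`
    when a mandatory column is absent and :class:`CohortValidationError` on
    duplicate patient ids or impossible outcome codings.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise CohortSchemaError(f"mandatory column(s) missing from header: {', '.join(missing_cols)}")
    for col in SCHEMA_COLUMNS:
        if col not in raw.columns:
            raw[col] = ""
    extra = [c for c in raw.columns if c not in SCHEMA_COLUMNS]
    raw = raw[list(SCHEMA_COLUMNS)]
    if extra:
        pass  # unknown columns are ignored, not an error

    report: dict[str, int] = {}

    def _bump(col):
        report[col] = report.get(col, 0) + 1

    n = len(raw)
    out: dict[str, object] = {}
    out["patient_id"] = raw["patient_id"].str.strip()
    if (out["patient_id"] == "").any():
        raise CohortValidationError("patient_id is mandatory and must be non-empty")
    dupes = out["patient_id"][out["patient_id"].duplicated()].unique().tolist()
    if dupes:
        raise CohortValidationError(f"duplicate patient_id values: {dupes}")

    for col in _NUMERIC_COLUMNS:
        vals = np.full(n, np.nan)
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell == "":
                continue
            try:
                vals[i] = float(cell)
            except ValueError:
                _bump(col)
        out[col] = vals

    for col in _BOOL_COLUMNS:
        parsed = []
        for cell in raw[col]:
            cell = cell.strip()
            if cell == "":
                parsed.append(None)
                continue
            b = _parse_bool(cell)
            if b is None:
                _bump(col)
            parsed.append(b)
        out[col] = pd.array(parsed, dtype="boolean")

    for col in ("sex", "tumor_site", "site_risk_override"):
        cleaned = raw[col].str.strip().str.lower()
        out[col] = pd.array([c if c else None for c in cleaned], dtype="string")

    events = np.full(n, np.nan)
    for i, cell in enumerate(raw["event"]):
        cell = cell.strip()
        if cell == "":
            continue
        try:
            e = int(float(cell))
        except ValueError:
            _bump("event")
            continue
        if e not in (0, 1, 2):
            _bump("event")
            continue
        events[i] = e
    out["event"] = events

    # sanity bounds: reject implausible lab/anthropometric values
    for col, (lo, hi) in (("bmi", _BMI_BOUNDS), ("hemoglobin_g_dl", _HGB_BOUNDS)):
        vals = out[col]
        bad = (~np.isnan(vals)) & ((vals <= lo) | (vals >= hi))
        for _ in range(int(bad.sum())):
            _bump(col)
        vals[bad] = np.nan

    time = out["time_months"]
    bad_time = (~np.isnan(time)) & (time < 0)
    if bad_time.any():
        raise CohortValidationError("time_months must be non-negative")
    ev = out["event"]
    zero_time_event = (~np.isnan(ev)) & (ev != 0) & (~np.isnan(time)) & (time <= 0)
    if zero_time_event.any():
        raise CohortValidationError("records with an event (VTE or death) must have time_months > 0")
    age = out["age_years"]
    if ((~np.isnan(age)) & (age < 0)).any():
        raise CohortValidationError("age_years must be non-negative")

    data = pd.DataFrame(out)[list(SCHEMA_COLUMNS)]
    return Cohort(data=data, provenance=provenance or str(path), parse_report=report)


def write_cohort(cohort: Cohort, path, delimiter: str = ",") -> None:
    """Write a cohort back to delimited text (missing values as empty cells).

    Booleans are emitted as 1/0 so a round trip through :func:`read_cohort`
    reproduces every field value exactly.
    """
    df = cohort.data.copy()
    for col in _BOOL_COLUMNS:
        df[col] = df[col].map(lambda b: "" if b is pd.NA else ("1" if b else "0"))
    df["event"] = df["event"].map(lambda e: "" if np.isnan(e) else str(int(e)))
    for col in _NUMERIC_COLUMNS:
        df[col] = df[col].map(lambda v: "" if (isinstance(v, float) and np.isnan(v)) else repr(float(v)))
    df = df.fillna("")
    df.to_csv(path, sep=delimiter, index=False, lineterminator="\n")


def _onkotev_inputs_complete(row, config: scoring.ScoreConfig) -> bool:
    """True when every input of the validation analysis is present.

    Required: the Khorana components (to decide the >2 flag), the three other
    ONKOTEV flags, and the outcome pair.  Any missing Khorana component makes
    the >2 flag missing, even when the flag would be logically forced.
    """
    if scoring.khorana_components_from_record(row, config) is None:
        return False
    for col in ("metastatic", "vascular_lymphatic_compression", "prior_vte"):
        v = row[col]
        if v is None or v is pd.NA:
            return False
    if isinstance(row["time_months"], float) and math.isnan(row["time_months"]):
        return False
    if isinstance(row["event"], float) and math.isnan(row["event"]):
        return False
    return True


def complete_case_filter(cohort: Cohort, config: scoring.ScoreConfig = scoring.DEFAULT_SCORE_CONFIG) -> Cohort:
    """Drop records that cannot contribute to the score validation.

    A record is retained only when the ONKOTEV score and the outcome are both
    computable: all Khorana inputs, the metastasis/compression/prior-VTE
    flags, and (time, event) must be non-missing.
    """
    keep = cohort.data.apply(lambda row: _onkotev_inputs_complete(row, config), axis=1)
    keep = np.asarray(keep, dtype=bool) if len(cohort.data) else np.zeros(0, dtype=bool)
    removed = int((~keep).sum())
    entry = FilterLogEntry(
        name="complete_case",
        n_removed=removed,
        reason="missing ONKOTEV score input or outcome",
    )
    return cohort._with_data(cohort.data.loc[keep], entry)


def eligibility_filter(cohort: Cohort, min_age: float = 18.0) -> Cohort:
    """Apply the eligibility rules: no baseline anticoagulation, age >= 18.

    Each rule's removals are logged separately.  Records with missing age or
    anticoagulation status are retained by this filter (missingness is the
    complete-case filter's concern).
    """
    data = cohort.data
    ac = data["on_anticoagulation"]
    on_ac = np.asarray(ac.fillna(False), dtype=bool)
    out = cohort._with_data(
        data.loc[~on_ac],
        FilterLogEntry("on_anticoagulation", int(on_ac.sum()), "receiving anticoagulation therapy"),
    )
    age = np.asarray(out.data["age_years"], dtype=float)
    underage = (~np.isnan(age)) & (age < min_age)
    return out._with_data(
        out.data.loc[~underage],
        FilterLogEntry("age_minimum", int(underage.sum()), f"younger than {min_age:g} years"),
    )


def _pct(count: int, denom: int) -> float:
    return round(100.0 * count / denom, 1) if denom else float("nan")


def summarize_cohort(cohort: Cohort, config: scoring.ScoreConfig = scoring.DEFAULT_SCORE_CONFIG) -> pd.DataFrame:
    """Tabulate the cohort the way validation reports present it.

    Returns a long table with columns (block, category, count, percent):
    tumor-site frequencies, each Khorana component, the Khorana score
    distribution with the derived <=2 / >2 split, each ONKOTEV component, and
    the ONKOTEV score and stratum distributions.  Percentages are over the
    non-missing denominator of each block, printed to one decimal.
    """
    rows: list[tuple[str, str, int, float]] = []
    if len(cohort) == 0:
        return pd.DataFrame(columns=["block", "category", "count", "percent"])

    scored = scoring.score_cohort(cohort.data, config)

    site = scored["tumor_site"].dropna()
    for label, cnt in site.value_counts().sort_index().items():
        rows.append(("tumor_site", str(label), int(cnt), _pct(int(cnt), len(site))))

    comps = [scoring.khorana_components_from_record(row, config) for _, row in scored.iterrows()]

    def _component_block(name, values):
        known = [v for v in values if v is not None]
        n_yes = sum(bool(v) for v in known)
        rows.append((name, "no", len(known) - n_yes, _pct(len(known) - n_yes, len(known))))
        rows.append((name, "yes", n_yes, _pct(n_yes, len(known))))

    _component_block("anemia_or_esa", [c.anemia_or_esa if c else None for c in comps])
    _component_block("leukocytosis", [c.leukocytosis if c else None for c in comps])
    _component_block("thrombocytosis", [c.thrombocytosis if c else None for c in comps])
    _component_block("obesity", [c.obesity if c else None for c in comps])

    risk = [c.site_risk if c else None for c in comps]
    known_risk = [r for r in risk if r is not None]
    for level in scoring.SITE_RISK_LEVELS:
        cnt = sum(r == level for r in known_risk)
        rows.append(("tumor_risk", level, cnt, _pct(cnt, len(known_risk))))

    kscores = scored["khorana_score"].dropna().astype(int)
    for s in range(0, 7):
        cnt = int((kscores == s).sum())
        if cnt or s <= 5:
            rows.append(("khorana_score", str(s), cnt, _pct(cnt, len(kscores))))
    n_gt2 = int((kscores > 2).sum())
    rows.append(("khorana_flag", "<=2", len(kscores) - n_gt2, _pct(len(kscores) - n_gt2, len(kscores))))
    rows.append(("khorana_flag", ">2", n_gt2, _pct(n_gt2, len(kscores))))

    for col, name in (
        ("metastatic", "metastatic"),
        ("vascular_lymphatic_compression", "compression"),
        ("prior_vte", "prior_vte"),
    ):
        vals = scored[col]
        known = vals.dropna()
        n_yes = int(known.sum())
        rows.append((name, "no", len(known) - n_yes, _pct(len(known) - n_yes, len(known))))
        rows.append((name, "yes", n_yes, _pct(n_yes, len(known))))

    oscores = scored["onkotev_score"].dropna().astype(int)
    for s in range(0, 5):
        cnt = int((oscores == s).sum())
        rows.append(("onkotev_score", str(s), cnt, _pct(cnt, len(oscores))))
    strata = scored["onkotev_stratum"].dropna()
    for label in scoring.ONKOTEV_STRATA:
        cnt = int((strata == label).sum())
        rows.append(("onkotev_stratum", label, cnt, _pct(cnt, len(strata))))

    return pd.DataFrame(rows, columns=["block", "category", "count", "percent"])
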