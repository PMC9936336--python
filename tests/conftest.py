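import numpy as np
import pandas as pd
import pytest

from catrisk.cohort_io import SCHEMA_COLUMNS, Cohort


def make_cohort_frame(n, **overrides):
    """A fully observed, score-computable cohort table with benign defaults."""
    base = {
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "age_years": 60.0,
        "sex": "female",
        "bmi": 24.0,
        "tumor_site": "breast",
        "site_risk_override": None,
        "hemoglobin_g_dl": 13.0,
        "uses_rbc_growth_factors": False,
        "leukocytes_per_ul": 7000.0,
        "platelets_per_ul": 250000.0,
        "metastatic": False,
        "vascular_lymphatic_compression": False,
        "prior_vte": False,
        "on_anticoagulation": False,
        "time_months": 12.0,
        "event": 0.0,
    }
    base.update(overrides)
    def _broadcast(v):
        if isinstance(v, (list, np.ndarray, pd.Series, pd.api.extensions.ExtensionArray)):
            return v
        return [v] * n

    df = pd.DataFrame({col: _broadcast(base[col]) for col in SCHEMA_COLUMNS})
    for col in ("uses_rbc_growth_factors", "metastatic", "vascular_lymphatic_compression", "prior_vte", "on_anticoagulation"):
        df[col] = pd.array(df[col], dtype="boolean")
    for col in ("sex", "tumor_site", "site_risk_override"):
        df[col] = pd.array(df[col], dtype="string")
    for col in ("age_years", "bmi", "hemoglobin_g_dl", "leukocytes_per_ul", "platelets_per_ul", "time_months", "event"):
        df[col] = pd.array(df[col], dtype="float64")
    return df


@pytest.fixture
def cohort_factory():
    def _make(n, **overrides):
        return Cohort(data=make_cohort_frame(n, **overrides), provenance="test")

    return _make


@pytest.fixture
def csv_cohort(tmp_path):
    """Write a small well-formed cohort file and return its path."""
    path = tmp_path / "cohort.csv"
    df = make_cohort_frame(3, time_months=[3.0, 6.0, 9.0], event=[1.0, 2.0, 0.0])
    lines = [",".join(SCHEMA_COLUMNS)]
    for _, row in df.iterrows():
        cells = []
        for col in SCHEMA_COLUMNS:
            v = row[col]
            if v is None or v is pd.NA:
                cells.append("")
            elif isinstance(v, (bool, np.bool_)):
                cells.append("1" if v else "0")
            elif col == "event":
                cells.append(str(int(v)))
            else:
                cells.append(str(v))
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path
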