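"""Time-dependent ROC analysis for an ordinal risk marker under competing
risks.

The cumulative-cases / dynamic-controls definition is used at each landmark
horizon tau: cases are subjects with a cause-1 (VTE) event in (0, tau],
controls are subjects still event-free beyond tau.  Subjects whose first
event by tau is the competing one (death) are, by default, kept as
non-cases -- the definition consistent with a CIF-based interpretation of
sensitivity -- with an option to exclude them instead.  Censoring is handled
by inverse-probability-of-censoring weights from the Kaplan-Meier estimate
of the censoring distribution on the pooled sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .competing_risks import SurvivalData, _censoring_km, _step_eval

__all__ = ["TimeDependentAUC", "td_auc", "td_roc_curve"]


@dataclass
class TimeDependentAUC:
    horizon_months: float
    auc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    defined: bool = True


def _frac_below(queries: np.ndarray, x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted fraction of sample ``(x, w)`` strictly below each query,
    counting weight exactly at the query with factor one half."""
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    cum = np.concatenate([[0.0], np.cumsum(ws)])
    below = cum[np.searchsorted(xs, queries, side="left")]
    below_or_eq = cum[np.searchsorted(xs, queries, side="right")]
    return (below + 0.5 * (below_or_eq - below)) / cum[-1]


def _case_control_weights(data: SurvivalData, horizon: float, include_competing: bool):
    """Case/control masks and IPCW weights at the horizon.

    Cases get weight 1/G(T_i-); event-free controls 1/G(tau); competing-event
    controls (when included) 1/G(T_i-).
    """
    t, e = data.time, data.event
    gt, gs = _censoring_km(t, e)
    g_left = np.asarray(_step_eval(gt, gs, t, left=True), dtype=float)
    g_floor = gs[gs > 0].min() if np.any(gs > 0) else 1.0
    g_left = np.where(g_left > 0, g_left, g_floor)
    g_tau = float(_step_eval(gt, gs, np.asarray([horizon]))[0])
    if g_tau <= 0:
        g_tau = g_floor

    case = (e == 1) & (t <= horizon)
    control = t > horizon
    weights = np.zeros(len(t))
    weights[case] = 1.0 / g_left[case]
    weights[control] = 1.0 / g_tau
    if include_competing:
        dead = (e == 2) & (t <= horizon)
        control = control | dead
        weights[dead] = 1.0 / g_left[dead]
    return case, control, weights


def td_auc(
    data: SurvivalData,
    marker: np.ndarray,
    horizon: float,
    include_competing_as_controls: bool = True,
    conf_level: float = 0.95,
) -> TimeDependentAUC:
    """IPCW cumulative/dynamic AUC of ``marker`` at ``horizon`` months.

    The point estimate is the weighted probability that a randomly drawn
    case carries a higher marker value than a randomly drawn control, ties
    counting one half.  The variance treats the censoring weights as known
    (two-sample weighted U-statistic projection); the CI is Wald, clipped to
    [0, 1].  With no cases or no controls at the horizon the result is
    flagged undefined and the AUC is NaN.
    """
    marker = np.asarray(marker, dtype=float)
    if marker.shape[0] != data.n:
        raise ValueError("marker must have length n")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if horizon > data.time.max():
        return TimeDependentAUC(horizon, float("nan"), float("nan"), float("nan"), 0, 0, defined=False)
    case, control, w = _case_control_weights(data, horizon, include_competing_as_controls)
    n_cases, n_controls = int(case.sum()), int(control.sum())
    if n_cases == 0 or n_controls == 0:
        return TimeDependentAUC(horizon, float("nan"), float("nan"), float("nan"), n_cases, n_controls, defined=False)

    mc, wc = marker[case], w[case]
    md, wd = marker[control], w[control]
    W_c, W_d = wc.sum(), wd.sum()
    # q_i: weighted fraction of controls below case i (ties half);
    # r_j: weighted fraction of cases above control j (ties half)
    q = _frac_below(mc, md, wd)
    r = 1.0 - _frac_below(md, mc, wc)
    auc = float(np.sum(wc * q) / W_c)

    var = float(np.sum((wc * (q - auc)) ** 2) / W_c**2 + np.sum((wd * (r - auc)) ** 2) / W_d**2)
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return TimeDependentAUC(
        horizon_months=float(horizon),
        auc=auc,
        ci_low=max(0.0, auc - half),
        ci_high=min(1.0, auc + half),
        n_cases=n_cases,
        n_controls=n_controls,
    )


def td_roc_curve(
    data: SurvivalData,
    marker: np.ndarray,
    horizon: float,
    include_competing_as_controls: bool = True,
) -> np.ndarray:
    """Stepwise (FPR, TPR) points of the time-dependent ROC at ``horizon``.

    Thresholds sweep the distinct marker values from high to low (rule:
    positive when marker >= threshold); endpoints (0,0) and (1,1) are
    included.  The trapezoidal area under the returned polyline equals the
    tie-corrected :func:`td_auc` point estimate.
    """
    marker = np.asarray(marker, dtype=float)
    case, control, w = _case_control_weights(data, horizon, include_competing_as_controls)
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError("ROC undefined: no cases or no controls at the horizon")
    thresholds = np.unique(marker)[::-1]
    wc_tot = w[case].sum()
    wd_tot = w[control].sum()
    pts = [(0.0, 0.0)]
    for c in thresholds:
        pos = marker >= c
        tpr = w[case & pos].sum() / wc_tot
        fpr = w[control & pos].sum() / wd_tot
        pts.append((fpr, tpr))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return np.array(pts)
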