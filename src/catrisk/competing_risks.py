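"""Competing-risks estimators: cumulative incidence, K-sample testing,
Fine-Gray regression, and incidence-rate arithmetic.

The event coding throughout is 0 = censored, 1 = event of interest (VTE),
2 = competing event observed first (death).  The cumulative incidence
function (CIF) is estimated by the product-limit (Aalen-Johansen /
Kalbfleisch-Prentice) form

    F_k(t) = sum_{t_i <= t} S(t_i-) * d_k(t_i) / n(t_i),

where ``S`` is the all-cause Kaplan-Meier survivor, ``d_k`` the cause-k
events and ``n`` the number at risk.  Pointwise variance uses the standard
counting-process (delta-method) estimator and 95% limits are formed on the
log(-log) scale so they stay inside [0, 1].

Group differences in the CIF are tested with the score test of the
inverse-probability-of-censoring-weighted (IPCW) subdistribution partial
likelihood -- the regression formulation of Gray's K-sample test -- which
reduces exactly to the log-rank test when there is neither censoring nor a
competing cause.  The same weighted partial likelihood, maximized by
Newton-Raphson, yields the Fine-Gray subdistribution hazard model: subjects
failing from the competing cause remain in later risk sets with weight
G(t)/G(T_i), G being the Kaplan-Meier estimate of the censoring
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalData",
    "CIFEstimate",
    "GrayTestResult",
    "FineGrayFit",
    "estimate_cif",
    "cif_at",
    "gray_test",
    "fine_gray_fit",
    "incidence_rate",
]


@dataclass
class SurvivalData:
    """Analysis-ready follow-up arrays for one cohort.

    time
        positive follow-up times (months).
    event
        0 censored, 1 cause of interest, 2 competing cause.
    group
        optional categorical labels (e.g. the ONKOTEV stratum).
    covariates
        optional numeric design matrix with named columns.
    """

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = self.time.shape[0]
        if n < 1:
            raise ValueError("SurvivalData requires at least one subject")
        if self.event.shape[0] != n:
            raise ValueError("time and event must have equal length")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("all times must be finite and > 0")
        if not np.isin(self.event, (0, 1, 2)).all():
            raise ValueError("event codes must be in {0, 1, 2}")
        if self.group is not None:
            self.group = np.asarray(self.group)
            if self.group.shape[0] != n:
                raise ValueError("group must have length n")
        if self.covariates is not None:
            self.covariates = pd.DataFrame(self.covariates)
            if len(self.covariates) != n:
                raise ValueError("covariates must have n rows")
            if self.covariates.isna().any().any():
                raise ValueError("covariates must not contain missing values")

    @property
    def n(self) -> int:
        return len(self.time)

    @classmethod
    def from_cohort(
        cls,
        data: pd.DataFrame,
        group: str | None = None,
        covariates: list[str] | None = None,
    ) -> "SurvivalData":
        """Build survival arrays from a (scored) cohort table."""
        time = np.asarray(data["time_months"], dtype=float)
        event = np.asarray(data["event"], dtype=float).astype(int)
        grp = None if group is None else np.asarray(data[group].astype(str))
        cov = None
        if covariates:
            cov = data[covariates].astype(float).reset_index(drop=True)
        return cls(time=time, event=event, group=grp, covariates=cov)


@dataclass
class CIFEstimate:
    """Stepwise cumulative incidence for one cause with pointwise 95% CIs."""

    cause: int
    times: np.ndarray
    cif: np.ndarray
    variance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int = 0


@dataclass
class GrayTestResult:
    statistic: float
    df: int
    p_value: float
    groups: tuple = ()


@dataclass
class FineGrayFit:
    """Fitted Fine-Gray model: one row of output per covariate."""

    names: list[str]
    coefficients: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    n: int
    n_events: int
    n_competing: int
    converged: bool
    n_iterations: int
    separation: bool = False
    log_likelihood: float = float("nan")

    def summary(self) -> pd.DataFrame:
        """Result table mirroring the usual published layout (HR, 95% CI, p)."""
        return pd.DataFrame(
            {
                "variable": self.names,
                "coef": self.coefficients,
                "se": self.se,
                "hr": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_values,
            }
        )


# ---------------------------------------------------------------------------
# Kaplan-Meier building blocks
# ---------------------------------------------------------------------------


def _km_curve(time: np.ndarray, is_event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survivor of ``is_event`` times.

    Ties: events are processed before censorings at the same time, so the
    risk set at t counts every subject with T >= t.  Returns the distinct
    event times and the survivor value just after each.
    """
    order = np.argsort(time, kind="stable")
    t, e = time[order], np.asarray(is_event, dtype=bool)[order]
    ut = np.unique(t[e])
    n_at_risk = len(t) - np.searchsorted(t, ut, side="left")
    d = np.array([np.sum(e[t == u]) for u in ut], dtype=float)
    surv = np.cumprod(1.0 - d / n_at_risk)
    return ut, surv


def _step_eval(times: np.ndarray, values: np.ndarray, t, left: bool = False, start: float = 1.0):
    """Evaluate a right-continuous step function; ``left`` gives the t- limit."""
    side = "left" if left else "right"
    idx = np.searchsorted(times, np.asarray(t, dtype=float), side=side)
    padded = np.concatenate([[start], values])
    return padded[idx]


def _censoring_km(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier of the censoring distribution (censorings as 'events').

    At tied times real events precede censorings, so the censoring risk set
    at t excludes subjects failing at t: the drop is d_c(t) / #{T > t or
    censored at t}.
    """
    is_cens = event == 0
    order = np.argsort(time, kind="stable")
    t = time[order]
    c = is_cens[order]
    ut = np.unique(t[c])
    surv = np.empty_like(ut)
    g = 1.0
    for j, u in enumerate(ut):
        at_risk = np.sum(t > u) + np.sum(c[t == u])
        d = np.sum(c[t == u])
        g *= 1.0 - d / at_risk if at_risk > 0 else 1.0
        surv[j] = g
    return ut, surv


# ---------------------------------------------------------------------------
# Cumulative incidence
# ---------------------------------------------------------------------------


def estimate_cif(data: SurvivalData, cause: int = 1, conf_level: float = 0.95):
    """Aalen-Johansen cumulative incidence of ``cause``.

    With ``data.group`` set, returns a dict mapping each group label to its
    own :class:`CIFEstimate`; otherwise a single estimate.  All-censored
    data yield an identically-zero CIF with empty step arrays.
    """
    if cause not in (1, 2):
        raise ValueError("cause must be 1 or 2")
    if data.group is not None:
        out = {}
        for level in pd.unique(data.group):
            mask = data.group == level
            sub = SurvivalData(time=data.time[mask], event=data.event[mask])
            out[level] = estimate_cif(sub, cause=cause, conf_level=conf_level)
        return out

    t, e = data.time, data.event
    any_event = e != 0
    ut = np.unique(t[any_event])
    if ut.size == 0:
        z = np.zeros(0)
        return CIFEstimate(cause, z, z.copy(), z.copy(), z.copy(), z.copy(), n=data.n)

    ts = np.sort(t)
    n_at_risk = len(t) - np.searchsorted(ts, ut, side="left")
    d_all = np.array([np.sum(any_event[t == u]) for u in ut], dtype=float)
    d_cause = np.array([np.sum((e == cause) & (t == u)) for u in ut], dtype=float)

    surv = np.cumprod(1.0 - d_all / n_at_risk)
    surv_left = np.concatenate([[1.0], surv[:-1]])
    jumps = surv_left * d_cause / n_at_risk
    cif = np.cumsum(jumps)

    # delta-method pointwise variance (Marubini-Valsecchi form)
    m = len(ut)
    with np.errstate(divide="ignore", invalid="ignore"):
        term_a = np.where(n_at_risk > d_all, d_all / (n_at_risk * (n_at_risk - d_all)), 0.0)
    term_b = surv_left**2 * ((n_at_risk - d_cause) / n_at_risk) * d_cause / n_at_risk**2
    term_c = surv_left * d_cause / n_at_risk**2
    diff = cif[:, None] - cif[None, :]  # diff[j, l] = F(t_j) - F(t_l)
    lower = np.tril(np.ones((m, m)))
    var = (
        (diff**2 * term_a[None, :] * lower).sum(axis=1)
        + np.cumsum(term_b)
        - 2.0 * (diff * term_c[None, :] * lower).sum(axis=1)
    )
    var = np.maximum(var, 0.0)

    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    se = np.sqrt(var)
    lo = np.zeros(m)
    hi = np.zeros(m)
    pos = (cif > 0) & (cif < 1)
    # log(-log) complementary transform keeps the bounds inside [0, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_se = np.where(pos, se / np.abs(cif * np.log(cif)), 0.0)
    lo[pos] = cif[pos] ** np.exp(z * theta_se[pos])
    hi[pos] = cif[pos] ** np.exp(-z * theta_se[pos])
    lo[cif >= 1] = 1.0
    hi[cif >= 1] = 1.0
    hi[(cif == 0)] = 0.0
    return CIFEstimate(cause, ut, cif, var, lo, hi, n=data.n)


def cif_at(est: CIFEstimate, t: float) -> tuple[float, float, float]:
    """Right-continuous lookup of (point, ci_low, ci_high) at time ``t``."""
    if t < 0:
        raise ValueError("t must be >= 0")
    idx = int(np.searchsorted(est.times, float(t), side="right"))
    if idx == 0:
        return (0.0, 0.0, 0.0)
    return (float(est.cif[idx - 1]), float(est.ci_low[idx - 1]), float(est.ci_high[idx - 1]))


# ---------------------------------------------------------------------------
# Fine-Gray weighted partial likelihood machinery
# ---------------------------------------------------------------------------


class _FGData:
    """Precomputed pieces of the IPCW subdistribution risk set.

    At each distinct cause-1 event time u_j, a subject contributes weight 1
    while still under observation (T_i >= u_j) and, after a competing event,
    weight G(u_j-)/G(T_i-); all other subjects contribute 0.
    """

    def __init__(self, time, event, X, cause=1):
        self.n, self.p = X.shape
        if cause == 2:  # analyse cause 2 by swapping the codes
            event = np.where(event == 1, 2, np.where(event == 2, 1, 0))
        self.time, self.event, self.X = time, event, X

        gt, gs = _censoring_km(time, event)
        self.u = np.unique(time[event == 1])
        if self.u.size == 0:
            raise ValueError("no events of the target cause")
        g_at_u = np.asarray(_step_eval(gt, gs, self.u, left=True), dtype=float)
        g_at_death = np.asarray(_step_eval(gt, gs, time, left=True), dtype=float)
        # guard: a death after the last censoring time keeps a positive weight
        g_floor = gs[gs > 0].min() if np.any(gs > 0) else 1.0
        self.g_at_u = np.where(g_at_u > 0, g_at_u, g_floor)
        self.g_at_death = np.where(g_at_death > 0, g_at_death, g_floor)

        self.d = np.array([np.sum((event == 1) & (time == uu)) for uu in self.u], dtype=float)
        self.sx = np.vstack([(X[(event == 1) & (time == uu)]).sum(axis=0) for uu in self.u])

        # sort orders reused every Newton iteration
        self._order_all = np.argsort(time, kind="stable")
        self._t_sorted = time[self._order_all]
        self._nat_idx = np.searchsorted(self._t_sorted, self.u, side="left")

        death = event == 2
        self._death_mask = death
        self._order_death = np.argsort(time[death], kind="stable")
        td_sorted = time[death][self._order_death]
        self._ext_idx = np.searchsorted(td_sorted, self.u, side="left")
        self.a_death = 1.0 / self.g_at_death[death][self._order_death]

        self.n_events = int(np.sum(event == 1))
        self.n_competing = int(np.sum(event == 2))

    def _suffix(self, arr):
        """suffix[k] = sum(arr[k:]) for a (n, q) array."""
        return np.vstack([np.cumsum(arr[::-1], axis=0)[::-1], np.zeros((1, arr.shape[1]))])

    def sums(self, beta, need_s2=True):
        """S0, S1 (and S2) of the weighted risk set at each event time."""
        eta = self.X @ beta
        eta = np.clip(eta, -700, 700)
        r = np.exp(eta)
        p = self.p

        cols = [r[:, None], r[:, None] * self.X]
        if need_s2:
            xx = np.einsum("ij,ik->ijk", self.X, self.X).reshape(self.n, p * p)
            cols.append(r[:, None] * xx)
        M = np.concatenate(cols, axis=1)

        nat = self._suffix(M[self._order_all])[self._nat_idx]

        Md = M[self._death_mask][self._order_death] * self.a_death[:, None]
        prefix = np.vstack([np.zeros((1, M.shape[1])), np.cumsum(Md, axis=0)])
        ext = prefix[self._ext_idx]

        tot = nat + self.g_at_u[:, None] * ext
        S0 = tot[:, 0]
        S1 = tot[:, 1 : 1 + p]
        S2 = tot[:, 1 + p :].reshape(-1, p, p) if need_s2 else None
        return S0, S1, S2, r

    def score_hessian(self, beta):
        S0, S1, S2, _ = self.sums(beta)
        xbar = S1 / S0[:, None]
        U = (self.sx - self.d[:, None] * xbar).sum(axis=0)
        H = np.einsum("j,jkl->kl", self.d, S2 / S0[:, None, None]) - np.einsum(
            "j,jk,jl->kl", self.d, xbar, xbar
        )
        loglik = float((self.sx @ beta).sum() - (self.d * np.log(S0)).sum())
        return U, H, loglik, xbar, S0

    def score_residuals(self, beta, xbar, S0):
        """Per-subject score contributions for the sandwich variance."""
        _, _, _, r = self.sums(beta, need_s2=False)
        c0 = self.d / S0
        c1 = self.d[:, None] * xbar / S0[:, None]

        # natural part: event times u_j <= T_i
        pos = np.searchsorted(self.u, self.time, side="right")
        cum0 = np.concatenate([[0.0], np.cumsum(c0)])
        cum1 = np.vstack([np.zeros(self.p), np.cumsum(c1, axis=0)])
        P = cum0[pos]
        Q = cum1[pos]

        # extended part for competing-event subjects: u_j > T_i, weight g_j * a_i
        death = self._death_mask
        suf0 = np.concatenate([np.cumsum((self.g_at_u * c0)[::-1])[::-1], [0.0]])
        suf1 = np.vstack([np.cumsum((self.g_at_u[:, None] * c1)[::-1], axis=0)[::-1], np.zeros(self.p)])
        pos_d = np.searchsorted(self.u, self.time[death], side="right")
        a_i = 1.0 / self.g_at_death[death]
        P = P.copy()
        Q = Q.copy()
        P[death] += a_i * suf0[pos_d]
        Q[death] += a_i[:, None] * suf1[pos_d]

        resid = -r[:, None] * (self.X * P[:, None] - Q)
        is_event = self.event == 1
        j_of = np.searchsorted(self.u, self.time[is_event])
        resid[is_event] += self.X[is_event] - xbar[j_of]
        return resid


def fine_gray_fit(
    data: SurvivalData,
    cause: int = 1,
    tol: float = 1e-9,
    max_iter: int = 100,
    variance: str = "robust",
    divergence_bound: float = 15.0,
    conf_level: float = 0.95,
) -> FineGrayFit:
    """Fit the Fine-Gray proportional subdistribution hazards model.

    Newton-Raphson (zero start, step-halving on likelihood decrease) on the
    IPCW-weighted partial likelihood; convergence when the max-norm of the
    score drops below ``tol``.  ``variance`` is ``"robust"`` (sandwich over
    per-subject score residuals, the default) or ``"model"`` (inverse
    information).  A coefficient wandering beyond ``divergence_bound`` is
    flagged as separation and the fit is reported unconverged rather than
    returning a silently meaningless estimate.
    """
    if data.covariates is None or data.covariates.shape[1] < 1:
        raise ValueError("fine_gray_fit requires at least one covariate")
    X = np.asarray(data.covariates, dtype=float)
    names = list(data.covariates.columns)
    fg = _FGData(data.time, data.event, X, cause=cause)

    p = X.shape[1]
    beta = np.zeros(p)
    converged = False
    separation = False
    n_iter = 0
    # the score is a sum over events, so its floating-point noise floor
    # scales with the event count; tolerate likelihood noise the same way
    score_tol = tol * max(1.0, fg.n_events)
    U, H, loglik, xbar, S0 = fg.score_hessian(beta)
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(U)) < score_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(H, U)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, U, rcond=None)[0]
        new_beta = beta + step
        U2, H2, ll2, xbar2, S02 = fg.score_hessian(new_beta)
        halves = 0
        noise = 1e-10 * (1.0 + abs(loglik))
        while ll2 < loglik - noise and halves < 30:
            step /= 2.0
            new_beta = beta + step
            U2, H2, ll2, xbar2, S02 = fg.score_hessian(new_beta)
            halves += 1
        beta, U, H, loglik, xbar, S0 = new_beta, U2, H2, ll2, xbar2, S02
        if np.max(np.abs(beta)) > divergence_bound:
            separation = True
            break
    else:
        n_iter = max_iter
    if not converged and np.max(np.abs(U)) < score_tol and not separation:
        converged = True

    Hinv = np.linalg.pinv(H)
    if variance == "robust":
        resid = fg.score_residuals(beta, xbar, S0)
        meat = resid.T @ resid
        cov = Hinv @ meat @ Hinv
    elif variance == "model":
        cov = Hinv
    else:
        raise ValueError("variance must be 'robust' or 'model'")
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    return FineGrayFit(
        names=names,
        coefficients=beta,
        se=se,
        hr=np.exp(beta),
        ci_low=np.exp(beta - z * se),
        ci_high=np.exp(beta + z * se),
        p_values=pvals,
        n=data.n,
        n_events=fg.n_events,
        n_competing=fg.n_competing,
        converged=converged and not separation,
        n_iterations=n_iter,
        separation=separation,
        log_likelihood=loglik,
    )


def gray_test(data: SurvivalData, cause: int = 1, rho: float = 0.0) -> GrayTestResult:
    """K-sample test for equality of cause-specific cumulative incidence.

    Implemented as the score test of the IPCW subdistribution partial
    likelihood with K-1 group indicators evaluated at beta = 0, optionally
    weighted by (1 - F_pooled(t-))**rho.  Without censoring and without
    competing events this is exactly the (Breslow-tie) log-rank statistic.
    The statistic is referred to a chi-square with K-1 degrees of freedom.
    """
    if data.group is None:
        raise ValueError("gray_test requires group labels")
    levels = pd.unique(data.group)
    counts = {lv: int(np.sum(data.group == lv)) for lv in levels}
    if any(c == 0 for c in counts.values()):
        raise ValueError("every group must be non-empty")
    if len(levels) < 2:
        raise ValueError("gray_test requires at least two groups")
    levels = sorted(levels, key=str)
    X = np.column_stack([(data.group == lv).astype(float) for lv in levels[1:]])
    fg = _FGData(data.time, data.event, X, cause=cause)

    beta0 = np.zeros(X.shape[1])
    S0, S1, S2, _ = fg.sums(beta0)
    xbar = S1 / S0[:, None]
    if rho != 0.0:
        pooled = estimate_cif(SurvivalData(time=data.time, event=data.event), cause=cause)
        f_left = _step_eval(pooled.times, pooled.cif, fg.u, left=True, start=0.0)
        w = (1.0 - np.asarray(f_left, dtype=float)) ** rho
    else:
        w = np.ones_like(fg.u)

    U = (w[:, None] * (fg.sx - fg.d[:, None] * xbar)).sum(axis=0)
    V = np.einsum("j,jkl->kl", w**2 * fg.d, S2 / S0[:, None, None]) - np.einsum(
        "j,jk,jl->kl", w**2 * fg.d, xbar, xbar
    )
    stat = float(U @ np.linalg.pinv(V) @ U)
    df = len(levels) - 1
    return GrayTestResult(
        statistic=max(stat, 0.0),
        df=df,
        p_value=float(stats.chi2.sf(max(stat, 0.0), df)),
        groups=tuple(levels),
    )


def incidence_rate(n_events: int, person_time_months: float) -> float:
    """Events per 100 person-months."""
    if person_time_months <= 0:
        raise ValueError("person_time_months must be > 0")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    return 100.0 * n_events / person_time_months
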