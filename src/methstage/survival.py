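"""Prognostic evaluation of biomarker candidates.

Kaplan-Meier estimation, log-rank testing and Cox proportional-hazards
fitting are delegated to lifelines; this module adds the
maximally-selected-rank-statistic (maxstat) dichotomization of a risk
score and the panel workflow used for multi-gene signatures: a
multivariate Cox fit yields per-gene weights, the linear predictor is
the per-sample risk score, maxstat picks the optimal high/low cut point
within a central quantile band (significance by permutation), and the
resulting groups are compared by log-rank for the prognosis p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "KMCurve",
    "CoxFit",
    "MaxstatResult",
    "SignaturePanel",
    "km_curve",
    "logrank_test",
    "cox_fit",
    "risk_score",
    "maxstat_cutpoint",
    "evaluate_panel",
]


@dataclass
class KMCurve:
    times: np.ndarray  # ordered event/censor times of the steps
    survival: np.ndarray  # S(t) at those times
    at_risk: np.ndarray
    median: float  # nan when S never reaches 0.5


@dataclass
class CoxFit:
    coefficients: pd.Series  # log hazard ratios
    se: pd.Series
    p: pd.Series  # Wald
    log_likelihood: float
    lr_p: float  # likelihood-ratio test of the whole model
    converged: bool


@dataclass
class MaxstatResult:
    cutpoint: float
    statistic: float  # max standardized log-rank |z|
    p: float  # permutation p-value
    candidate_cuts: np.ndarray
    minprop: float


@dataclass
class SignaturePanel:
    panel_id: str
    genes: list
    weights: pd.Series
    risk_scores: pd.Series
    cutpoint: float
    high_risk: pd.Series  # bool per sample: score > cut
    model_p: float  # multivariate likelihood-ratio p
    prognosis_p: float  # log-rank p of high vs low


def km_curve(times, events) -> KMCurve:
    """Product-limit survival estimate.

    Median survival is the first time at which S(t) drops to 0.5 or
    below; NaN when the curve never reaches 0.5 (e.g. all censored).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    grid = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()
    # drop the t=0 anchor row lifelines prepends unless 0 is a data time
    if grid[0] == 0 and 0 not in times:
        grid, surv = grid[1:], surv[1:]
        at_risk = tab["at_risk"].to_numpy()[1:]
    else:
        at_risk = tab["at_risk"].to_numpy()
    med = kmf.median_survival_time_
    return KMCurve(times=grid, survival=surv, at_risk=at_risk, median=float(med) if np.isfinite(med) else float("nan"))


def logrank_test(times_a, events_a, times_b, events_b):
    """Two-group log-rank test: (chi-square statistic, p-value)."""
    ev = np.concatenate([np.asarray(events_a), np.asarray(events_b)])
    if ev.sum() == 0:
        raise ValueError("log-rank requires at least one event")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(x: pd.DataFrame, times, events, ties: str = "efron") -> CoxFit:
    """Cox proportional-hazards regression (Efron ties by default).

    ``x`` is a sample x covariate frame.  Constant covariates are
    rejected; non-convergence or separation is surfaced via the
    ``converged`` flag rather than an exception where possible.
    """
    x = pd.DataFrame(x).copy()
    if (x.nunique(axis=0) <= 1).any():
        bad = x.columns[x.nunique(axis=0) <= 1].tolist()
        raise ValueError(f"constant covariate(s): {bad}")
    events = np.asarray(events, dtype=int)
    if events.sum() < x.shape[1] + 1:
        raise ValueError("too few events for the number of covariates")
    df = x.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = events
    cph = CoxPHFitter()
    converged = True
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:  # monotone likelihood / separation
        raise RuntimeError(f"Cox fit failed: {exc}") from exc
    lr = cph.log_likelihood_ratio_test()
    return CoxFit(
        coefficients=cph.params_,
        se=cph.standard_errors_,
        p=cph.summary["p"],
        log_likelihood=float(cph.log_likelihood_),
        lr_p=float(lr.p_value),
        converged=converged,
    )


def risk_score(fit: CoxFit, x: pd.DataFrame) -> pd.Series:
    """Linear predictor sum(beta_j * x_j), no centering or intercept."""
    x = pd.DataFrame(x)
    if list(x.columns) != list(fit.coefficients.index):
        try:
            x = x[list(fit.coefficients.index)]
        except KeyError as exc:
            raise ValueError("covariates do not match the fitted model") from exc
    return x @ fit.coefficients


def _logrank_z_by_cut(order_scores_high: np.ndarray, times: np.ndarray, events: np.ndarray):
    """Standardized log-rank z for each candidate split, vectorized.

    ``order_scores_high``: (n_samples x n_cuts) boolean, rows already
    sorted by ascending time, True = high-risk group.
    """
    n, c = order_scores_high.shape
    # at-risk counts just before each row's time: suffix counts
    g = order_scores_high.astype(float)
    n1_at_risk = np.cumsum(g[::-1], axis=0)[::-1]  # incl. current row
    n_at_risk = np.arange(n, 0, -1, dtype=float)
    d = events.astype(float)
    # handle tied event times: group rows by distinct time
    t_sorted = times
    # new time block starts here
    starts = np.r_[True, t_sorted[1:] != t_sorted[:-1]]
    block = np.cumsum(starts) - 1
    nblocks = block[-1] + 1
    # per block: deaths total, deaths in group1, at-risk totals at block start
    d_tot = np.zeros(nblocks)
    np.add.at(d_tot, block, d)
    d1 = np.zeros((nblocks, c))
    np.add.at(d1, block, g * d[:, None])
    first_idx = np.flatnonzero(starts)
    n_tot = n_at_risk[first_idx]
    n1 = n1_at_risk[first_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = n1 / n_tot[:, None]
        oe = (d1 - d_tot[:, None] * frac).sum(axis=0)
        valid = n_tot > 1
        v = (
            d_tot[valid, None]
            * frac[valid]
            * (1 - frac[valid])
            * ((n_tot[valid] - d_tot[valid]) / (n_tot[valid] - 1))[:, None]
        ).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(v > 0, oe / np.sqrt(v), 0.0)
    return z


def maxstat_cutpoint(
    score,
    times,
    events,
    minprop: float = 0.1,
    n_perm: int = 1000,
    seed: int | None = None,
) -> MaxstatResult:
    """Maximally selected rank statistic cut point for a risk score.

    Every distinct score value within the [minprop, 1-minprop] quantile
    band is a candidate threshold (high = score > threshold); the
    standardized two-group log-rank statistic is evaluated at each, and
    the maximizing |z| wins.  The reported cut point is the midpoint
    between the chosen threshold and the next distinct score, and the
    p-value comes from ``n_perm`` permutations of the scores.
    """
    score = np.asarray(score, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(score)
    if n < 10:
        raise ValueError("maxstat needs at least 10 samples")
    uniq = np.unique(score)
    if len(uniq) < 2:
        raise ValueError("score is constant; no cut point exists")
    order = np.argsort(times, kind="stable")
    t_s, e_s, s_s = times[order], events[order], score[order]
    # admissible thresholds: both groups hold at least minprop of samples
    n_low = np.searchsorted(np.sort(score), uniq, side="right")
    ok = (n_low >= minprop * n) & (n - n_low >= minprop * n)
    cuts = uniq[ok]
    if len(cuts) == 0:
        raise ValueError("no admissible cut point within the minprop band")
    g = s_s[:, None] > cuts[None, :]
    z = _logrank_z_by_cut(g, t_s, e_s)
    best = int(np.argmax(np.abs(z)))
    thr = cuts[best]
    above = uniq[uniq > thr]
    cutpoint = float((thr + above[0]) / 2.0) if len(above) else float(thr)
    obs = float(np.abs(z[best]))

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        zp = _logrank_z_by_cut(g[perm], t_s, e_s)
        if np.max(np.abs(zp)) >= obs:
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return MaxstatResult(cutpoint=cutpoint, statistic=obs, p=p, candidate_cuts=cuts, minprop=minprop)


def evaluate_panel(
    panel_id: str,
    genes,
    x: pd.DataFrame,
    times,
    events,
    minprop: float = 0.1,
    n_perm: int = 1000,
    seed: int | None = None,
) -> SignaturePanel:
    """Multi-gene signature evaluation.

    Multivariate Cox fit on the panel genes -> weights -> per-sample risk
    score -> maxstat dichotomization -> log-rank prognosis p between the
    high- and low-risk groups.  The multivariate model p is the
    likelihood-ratio test of the Cox fit.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in x.columns]
    if missing:
        raise ValueError(f"panel genes absent from covariates: {missing}")
    sub = x[genes]
    fit = cox_fit(sub, times, events)
    scores = risk_score(fit, sub)
    ms = maxstat_cutpoint(scores.to_numpy(), times, events, minprop=minprop, n_perm=n_perm, seed=seed)
    high = scores > ms.cutpoint
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    _, prognosis_p = logrank_test(times[high.to_numpy()], events[high.to_numpy()], times[~high.to_numpy()], events[~high.to_numpy()])
    return SignaturePanel(
        panel_id=panel_id,
        genes=genes,
        weights=fit.coefficients,
        risk_scores=scores,
        cutpoint=ms.cutpoint,
        high_risk=high,
        model_p=fit.lr_p,
        prognosis_p=prognosis_p,
    )
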