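"""Methylation-expression integration.

Promoter methylation typically represses transcription, so genes whose
methylation drives their expression show a negative methylation-
expression correlation.  The integration proceeds in three steps per
gene: (i) a Pearson correlation filter between per-sample gene
methylation (mean beta across the gene's probes) and expression, at the
conventional |r| >= 0.3 cutoff; (ii) a univariate Gaussian mixture model
of the cancer cases' M-values, whose component count (selected by BIC
over K = 1..3) represents the number of methylation states; and (iii) a
Wilcoxon rank-sum comparison of each methylation state against the
controls.  A gene passing all three is called a (stage-specific) driver,
with a differential-methylation (DM) value reported on the beta scale as
component mean minus control mean, positive for hypermethylation.

A companion model estimates expression from methylation with per-gene
linear maps, so that differential-expression analysis can be run where
only methylation was assayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .linmod import bh_adjust
from .preprocess import m_to_beta

__all__ = [
    "meth_expr_correlation",
    "GaussianMixture1D",
    "fit_mixture_em",
    "wilcoxon_ranksum",
    "driver_calls",
    "ExpressionFromMethylation",
    "estimate_expression",
]


def meth_expr_correlation(meth: pd.DataFrame, expr: pd.DataFrame, cutoff: float = 0.3) -> pd.DataFrame:
    """Per-gene Pearson correlation between methylation and expression.

    Rows are matched by gene, columns by sample (at least three shared
    samples required).  Genes with zero variance on either side have an
    undefined correlation and are skipped.  The ``selected`` flag marks
    genes at or above the |r| cutoff, regardless of sign.
    """
    genes = meth.index.intersection(expr.index)
    samples = meth.columns.intersection(expr.columns)
    if len(samples) < 3:
        raise ValueError("need at least three paired samples")
    rows = []
    for g in genes:
        x = meth.loc[g, samples].to_numpy(dtype=float)
        y = expr.loc[g, samples].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            continue  # r undefined for a constant vector
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append((g, r, len(samples)))
    out = pd.DataFrame(rows, columns=["gene", "r", "n"]).set_index("gene")
    out["selected"] = out["r"].abs() >= cutoff
    return out


# ---------------------------------------------------------------------------
# Univariate Gaussian mixture by EM
# ---------------------------------------------------------------------------


@dataclass
class GaussianMixture1D:
    """A fitted univariate Gaussian mixture (methylation states).

    ``loglik_trace`` is the per-iteration log-likelihood of the winning
    restart; EM guarantees it is non-decreasing.
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    bic: float
    converged: bool
    loglik_trace: np.ndarray
    responsibilities: np.ndarray = field(repr=False, default=None)

    @property
    def assignments(self) -> np.ndarray:
        return self.responsibilities.argmax(axis=1)


def _em_once(x, k, rng, max_iter, tol, var_floor):
    n = len(x)
    # k-means++-style spread of initial means over the data range
    means = rng.choice(x, size=k, replace=False).astype(float)
    var = np.full(k, max(x.var(), var_floor))
    weights = np.full(k, 1.0 / k)
    trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # E step
        logp = (
            np.log(weights)[None, :]
            - 0.5 * np.log(2 * np.pi * var)[None, :]
            - 0.5 * (x[:, None] - means[None, :]) ** 2 / var[None, :]
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        resp = np.exp(logp - lse[:, None])
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
        # M step
        nk = resp.sum(axis=0) + 1e-300
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, var_floor)
    return weights, means, var, float(trace[-1]), converged, np.array(trace), resp


def fit_mixture_em(
    values,
    k_max: int = 3,
    restarts: int = 5,
    seed: int | None = None,
    max_iter: int = 300,
    tol: float = 1e-8,
    var_floor: float = 1e-6,
) -> GaussianMixture1D:
    """Fit univariate Gaussian mixtures for K = 1..k_max, select by BIC.

    Each K is fitted by expectation-maximization from ``restarts`` random
    initialisations; the restart with the highest log-likelihood wins and
    the K minimising BIC = -2 logL + (3K - 1) log n is chosen.
    Non-convergence within ``max_iter`` returns the best restart with the
    ``converged`` flag cleared.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 10:
        raise ValueError("mixture fitting needs at least 10 samples")
    rng = np.random.default_rng(seed)
    best = None
    for k in range(1, k_max + 1):
        k_best = None
        for _ in range(restarts if k > 1 else 1):
            fit = _em_once(x, k, rng, max_iter, tol, var_floor)
            if k_best is None or fit[3] > k_best[3]:
                k_best = fit
        weights, means, var, ll, converged, trace, resp = k_best
        n_params = 3 * k - 1
        bic = -2.0 * ll + n_params * np.log(len(x))
        order = np.argsort(means)
        cand = GaussianMixture1D(
            k=k,
            weights=weights[order],
            means=means[order],
            variances=var[order],
            log_likelihood=ll,
            bic=bic,
            converged=converged,
            loglik_trace=trace,
            responsibilities=resp[:, order],
        )
        if best is None or cand.bic < best.bic:
            best = cand
    return best


def wilcoxon_ranksum(x, y):
    """Two-sided Wilcoxon rank-sum test.

    Returns the rank-sum statistic W of the first sample and the p-value:
    exact by enumeration when both samples have <= 8 observations and no
    ties, otherwise a tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= 8 and len(y) <= 8 and not ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0  # U -> rank sum
    return w, float(res.pvalue)


def driver_calls(
    stage: str,
    meth_m: pd.DataFrame,
    correlations: pd.DataFrame,
    stage_samples,
    control_samples,
    adj_p_max: float = 0.05,
    r_cutoff: float = 0.3,
    seed: int | None = None,
    restarts: int = 3,
) -> pd.DataFrame:
    """Stage-vs-control driver gene calls.

    For each gene passing the correlation filter, a Gaussian mixture is
    fitted to the stage samples' M-values; each methylation-state
    component is compared with the controls by Wilcoxon rank-sum, and
    p-values are BH-adjusted across all (gene, component) tests of the
    stage.  A gene is a driver when any component differs at adjusted
    p < ``adj_p_max``.  DM values are component mean minus control mean
    on the beta scale; positive DM is hypermethylation.
    """
    eligible = correlations.index[correlations["r"].abs() >= r_cutoff]
    eligible = meth_m.index.intersection(eligible)
    records = []
    for i, gene in enumerate(eligible):
        m_stage = meth_m.loc[gene, stage_samples].to_numpy(dtype=float)
        m_ctrl = meth_m.loc[gene, control_samples].to_numpy(dtype=float)
        gene_seed = None if seed is None else (seed + i) % (2**31 - 1)
        mix = fit_mixture_em(m_stage, restarts=restarts, seed=gene_seed)
        ctrl_beta_mean = float(m_to_beta(m_ctrl).mean())
        for comp in range(mix.k):
            members = m_stage[mix.assignments == comp]
            if len(members) == 0:
                continue
            w, p = wilcoxon_ranksum(members, m_ctrl)
            dm = float(m_to_beta(np.array([mix.means[comp]]))[0]) - ctrl_beta_mean
            records.append((gene, comp, mix.k, float(mix.means[comp]), dm, w, p))
    table = pd.DataFrame(
        records, columns=["gene", "component", "k", "component_mean_m", "dm", "statistic", "p"]
    )
    if len(table):
        table["adj_p"] = bh_adjust(table["p"].to_numpy())
        table["direction"] = np.where(table["dm"] > 0, "Hyper", "Hypo")
        table["driver"] = table["adj_p"] < adj_p_max
    else:
        table["adj_p"] = []
        table["direction"] = []
        table["driver"] = []
    table["stage"] = stage
    return table


# ---------------------------------------------------------------------------
# Expression estimated from methylation
# ---------------------------------------------------------------------------


@dataclass
class ExpressionFromMethylation:
    """Per-gene linear maps expression ~ methylation, with predictions."""

    coefficients: pd.DataFrame  # gene x (intercept, slope, r2)
    predictions: pd.DataFrame  # gene x test samples
    skipped: list


def estimate_expression(train_meth: pd.DataFrame, train_expr: pd.DataFrame, test_meth: pd.DataFrame) -> ExpressionFromMethylation:
    """Train per-gene simple linear regressions and predict expression.

    Genes with zero methylation variance in training are skipped (their
    slope is unidentifiable).  Training R^2 equals the squared Pearson
    correlation, an OLS identity surfaced for QC.
    """
    genes = train_meth.index.intersection(train_expr.index).intersection(test_meth.index)
    samples = train_meth.columns.intersection(train_expr.columns)
    if len(samples) < 10:
        raise ValueError("need at least 10 paired training samples")
    x = train_meth.loc[genes, samples].to_numpy(dtype=float)
    y = train_expr.loc[genes, samples].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    vx = (xc**2).mean(axis=1)
    vy = (yc**2).mean(axis=1)
    identifiable = vx > 0
    skipped = list(genes[~identifiable])
    genes = genes[identifiable]
    cov = (xc * yc).mean(axis=1)[identifiable]
    slope = cov / vx[identifiable]
    intercept = y.mean(axis=1)[identifiable] - slope * x.mean(axis=1)[identifiable]
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(vy[identifiable] > 0, cov**2 / (vx[identifiable] * vy[identifiable]), np.nan)
    coef_frame = pd.DataFrame({"intercept": intercept, "slope": slope, "r2": r2}, index=genes)
    coef_frame.index.name = "gene"
    preds = intercept[:, None] + slope[:, None] * test_meth.loc[genes].to_numpy(dtype=float)
    pred_frame = pd.DataFrame(preds, index=genes, columns=test_meth.columns)
    return ExpressionFromMethylation(coefficients=coef_frame, predictions=pred_frame, skipped=skipped)
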