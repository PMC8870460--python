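"""Per-feature linear modelling of stagewise methylation with
empirical-Bayes variance moderation.

The model for each feature g (probe or gene) is

    y_g = X b_g + e_g,   e_g ~ N(0, s2_g I)

where X is the stage design: controls contribute only to the intercept
and each stage I--IV is an indicator column, so the stage coefficients
are directly the mean differences from control (the "log fold-change"
of M-values).  Per-feature variances are moderated by shrinking towards
a pooled prior estimated by moment-matching the marginal distribution of
log sample variances (a scaled F under the hierarchical model), giving
moderated t-statistics with d0 + d_g degrees of freedom.

The same engine runs on the M-value matrix (probe- or gene-level) and on
the beta matrix (differentially-methylated-probe mode); only the input
scale differs.

A small statsmodels-flavoured front end is provided:
``StageLinearModel(matrix, samples).fit()`` returns a
:class:`StageLinearResults` carrying the fit, moderated statistics and
contrast tables, with a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignMatrix",
    "LinearFit",
    "ModeratedStats",
    "build_design",
    "fit_linear",
    "ebayes",
    "contrast_test",
    "bh_adjust",
    "stage_contrast_vector",
    "STAGE_ORDER",
    "INTERSTAGE_PAIRS",
    "StageLinearModel",
    "StageLinearResults",
]

STAGE_ORDER = ("I", "II", "III", "IV")
COEF_NAMES = ("intercept", "stageI", "stageII", "stageIII", "stageIV")

#: The six inter-stage pairs used in the second contrast tier.
INTERSTAGE_PAIRS = (("I", "II"), ("I", "III"), ("I", "IV"), ("II", "III"), ("II", "IV"), ("III", "IV"))


@dataclass
class DesignMatrix:
    """Indicator design: intercept (control baseline) + one column per stage."""

    values: np.ndarray  # samples x 5
    sample_ids: list
    coef_names: tuple = COEF_NAMES


@dataclass
class LinearFit:
    """Ordinary least-squares fit per feature."""

    coefficients: pd.DataFrame  # features x coefficients
    sigma2: pd.Series  # residual variance per feature
    df_residual: int
    stdev_unscaled: np.ndarray  # per-coefficient sqrt of (X'X)^-1 diagonal
    design: DesignMatrix


@dataclass
class ModeratedStats:
    """Empirical-Bayes moderated variance statistics."""

    d0: float  # prior degrees of freedom (may be inf)
    s0_2: float  # prior variance
    s2_post: pd.Series  # posterior (moderated) variance per feature
    df_total: float


def build_design(samples: pd.DataFrame) -> DesignMatrix:
    """Build the stage indicator design from a mapped sample sheet.

    Requires a ``parent_stage`` column; every group (control and each of
    the four stages) must be represented.
    """
    stages = samples["parent_stage"].to_numpy()
    for grp in ("CONTROL",) + STAGE_ORDER:
        if (stages == grp).sum() == 0:
            raise ValueError(f"design requires at least one sample in group {grp!r}")
    n = len(samples)
    x = np.zeros((n, 5))
    x[:, 0] = 1.0
    for k, stage in enumerate(STAGE_ORDER, start=1):
        x[:, k] = (stages == stage).astype(float)
    return DesignMatrix(values=x, sample_ids=list(samples["sample_id"]))


def fit_linear(m: pd.DataFrame, design: DesignMatrix) -> LinearFit:
    """Per-feature OLS against the stage design.

    Under indicator coding the stage coefficients are exactly
    (stage mean - control mean) and the intercept is the control mean.
    """
    x = design.values
    n, p = x.shape
    if m.shape[1] != n:
        raise ValueError("matrix columns and design rows disagree")
    if n <= p:
        raise ValueError("fewer samples than coefficients")
    y = m.to_numpy(dtype=float).T  # samples x features
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y  # p x features
    resid = y - x @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    coef = pd.DataFrame(beta.T, index=m.index, columns=COEF_NAMES)
    return LinearFit(
        coefficients=coef,
        sigma2=pd.Series(sigma2, index=m.index),
        df_residual=df,
        stdev_unscaled=np.sqrt(np.diag(xtx_inv)),
        design=design,
    )


def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def ebayes(fit: LinearFit, d0: float | None = None, var_floor: float = 1e-12) -> ModeratedStats:
    """Moderate per-feature variances towards a pooled prior.

    The prior degrees of freedom d0 and prior variance s0^2 are estimated
    by moment-matching the log sample variances: under the hierarchical
    model, z_g = log s2_g follows a location-shifted log-F whose mean and
    variance involve digamma/trigamma functions of d_g/2 and d0/2; the
    trigamma equation is inverted by Newton iteration.  The posterior
    variance is the precision-weighted blend

        s2_post = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g).

    ``d0`` may be forced (0 recovers ordinary t exactly; inf pools fully).
    If the trigamma moment estimate is non-positive the variances are
    consistent with a single common value and d0 = inf is used.
    """
    s2 = np.maximum(fit.sigma2.to_numpy(dtype=float), var_floor)
    if np.all(s2 <= var_floor):
        raise ValueError("all residual variances are zero; nothing to moderate")
    dg = fit.df_residual
    if d0 is None:
        if len(s2) < 10:
            raise ValueError("need >= 10 features to estimate the variance prior")
        z = np.log(s2)
        e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
        emean = float(e.mean())
        n = len(e)
        evar = float(((e - emean) ** 2).sum() / (n - 1)) - float(special.polygamma(1, dg / 2.0))
        if evar > 0:
            d0 = 2.0 * _trigamma_inverse(evar)
        else:
            d0 = np.inf
        if np.isfinite(d0):
            s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            s0_2 = float(np.exp(emean))
    else:
        d0 = float(d0)
        s0_2 = float(np.exp(np.mean(np.log(s2)))) if d0 > 0 else float("nan")

    if d0 == 0:
        s2_post = s2.copy()
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
    else:
        s2_post = (d0 * s0_2 + dg * s2) / (d0 + dg)
    return ModeratedStats(
        d0=d0,
        s0_2=s0_2,
        s2_post=pd.Series(s2_post, index=fit.sigma2.index),
        df_total=dg + d0,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def stage_contrast_vector(stage_a: str, stage_b: str | None = None) -> np.ndarray:
    """Contrast vector for stage_a vs control, or stage_a vs stage_b."""
    c = np.zeros(5)
    c[1 + STAGE_ORDER.index(stage_a)] = 1.0
    if stage_b is not None:
        c[1 + STAGE_ORDER.index(stage_b)] = -1.0
    return c


def contrast_test(fit: LinearFit, mod: ModeratedStats, contrast, label: str = "") -> pd.DataFrame:
    """Moderated t-test of a single contrast of the stage coefficients.

    Returns a per-feature table with the contrast estimate ``lfc``
    (M-units when run on an M matrix), moderated t, two-sided p, and the
    BH-adjusted p computed within this contrast.
    """
    c = np.asarray(contrast, dtype=float)
    if c.shape != (len(COEF_NAMES),):
        raise ValueError("contrast length must equal coefficient count")
    if np.all(c == 0):
        raise ValueError("zero contrast vector")
    lfc = fit.coefficients.to_numpy() @ c
    xtx_inv = np.linalg.inv(fit.design.values.T @ fit.design.values)
    u = float(np.sqrt(c @ xtx_inv @ c))
    se = u * np.sqrt(mod.s2_post.to_numpy())
    t = lfc / se
    df = min(mod.df_total, 1e6)  # t -> normal limit when the prior dominates
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {
            "lfc": lfc,
            "t": t,
            "p": p,
            "adj_p": bh_adjust(p),
            "contrast": label,
        },
        index=fit.coefficients.index,
    )


# ---------------------------------------------------------------------------
# Model / Results front end
# ---------------------------------------------------------------------------


class StageLinearModel:
    """Stagewise linear model of a feature x sample methylation matrix.

    Parameters
    ----------
    matrix : DataFrame
        Features (probes or genes) x samples; M values normally, beta
        values in DMP mode.
    samples : DataFrame
        Sample sheet with ``sample_id`` and ``parent_stage``; row order
        must match the matrix columns.
    """

    def __init__(self, matrix: pd.DataFrame, samples: pd.DataFrame):
        samples = samples.set_index("sample_id").loc[list(matrix.columns)].reset_index()
        self.matrix = matrix
        self.samples = samples
        self.design = build_design(samples)

    def fit(self, d0: float | None = None) -> "StageLinearResults":
        linear = fit_linear(self.matrix, self.design)
        mod = ebayes(linear, d0=d0)
        return StageLinearResults(self, linear, mod)


@dataclass
class StageLinearResults:
    model: StageLinearModel
    fit: LinearFit
    moderated: ModeratedStats
    _cache: dict = field(default_factory=dict)

    def contrast(self, stage_a: str, stage_b: str | None = None) -> pd.DataFrame:
        label = f"{stage_a}-CONTROL" if stage_b is None else f"{stage_a}-{stage_b}"
        if label not in self._cache:
            vec = stage_contrast_vector(stage_a, stage_b)
            self._cache[label] = contrast_test(self.fit, self.moderated, vec, label=label)
        return self._cache[label]

    def stage_vs_control(self) -> dict[str, pd.DataFrame]:
        """The four first-tier contrast tables keyed by stage."""
        return {s: self.contrast(s) for s in STAGE_ORDER}

    def interstage(self) -> dict[tuple[str, str], pd.DataFrame]:
        """The six second-tier inter-stage contrast tables."""
        return {(a, b): self.contrast(a, b) for a, b in INTERSTAGE_PAIRS}

    def summary(self, top: int = 10) -> str:
        lines = [
            "Stagewise linear model (empirical-Bayes moderated)",
            f"  features: {self.fit.coefficients.shape[0]}, samples: {self.model.matrix.shape[1]}",
            f"  residual df: {self.fit.df_residual}, prior df d0: {self.moderated.d0:.4g}, "
            f"prior variance s0^2: {self.moderated.s0_2:.4g}",
        ]
        for stage in STAGE_ORDER:
            tab = self.contrast(stage).sort_values("adj_p").head(top)
            lines.append(f"  top features, stage {stage} vs control:")
            for fid, row in tab.iterrows():
                lines.append(f"    {fid}\tlfc={row.lfc:+.3f}\tt={row.t:+.2f}\tadj_p={row.adj_p:.3g}")
        return "\n".join(lines)
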