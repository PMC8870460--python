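"""CpG-phenotype association by one-way ANOVA.

Each feature's methylation (beta values, following the convention of the
CpG-association tooling this mirrors) is tested against the five-level
phenotype (control, stages I--IV) with a fixed-effects one-way ANOVA.
Stage candidate lists combine the BH-adjusted ANOVA p-value with the
M-scale stage-vs-control log fold-change from the linear engine.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .linmod import STAGE_ORDER, bh_adjust

__all__ = ["anova_f", "anova_table", "assoc_stage_calls"]


def anova_f(values, groups):
    """One-way ANOVA of a single feature: F statistic and p-value.

    ``F = (between-group SS / (k-1)) / (within-group SS / (n-k))``; every
    group must contribute at least two samples.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = []
    for g in pd.unique(groups):
        v = values[groups == g]
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than two samples")
        samples.append(v)
    if len(samples) < 2:
        raise ValueError("ANOVA needs at least two groups")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def anova_table(matrix: pd.DataFrame, groups, method: str = "fdr_bh") -> pd.DataFrame:
    """Feature-wise one-way ANOVA across phenotype groups.

    Parameters
    ----------
    matrix : DataFrame
        Feature x sample values (beta scale by convention).
    groups : sequence
        Group label per sample (columns order).
    method : str
        Multiple-testing family: ``fdr_bh`` (default) or ``holm``.

    Returns
    -------
    DataFrame with F, df1, df2, p, adj_p per feature.
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least two groups")
    chunks = []
    for g in labels:
        sub = matrix.loc[:, groups == g]
        if sub.shape[1] < 2:
            raise ValueError(f"group {g!r} has fewer than two samples")
        chunks.append(sub.to_numpy(dtype=float))
    f, p = stats.f_oneway(*chunks, axis=1)
    if method == "fdr_bh":
        adj = bh_adjust(p)
    elif method == "holm":
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(p, method="holm")[1]
    else:
        raise ValueError(f"unknown correction method {method!r}")
    k, n = len(labels), matrix.shape[1]
    return pd.DataFrame(
        {"F": f, "df1": k - 1, "df2": n - k, "p": p, "adj_p": adj},
        index=matrix.index,
    )


def assoc_stage_calls(
    assoc: pd.DataFrame,
    stage_lfc: pd.DataFrame,
    adj_p_max: float = 0.001,
    lfc_min: float = 2.0,
) -> dict[str, pd.DataFrame]:
    """Per-stage candidate lists from the ANOVA + stage fold-changes.

    A feature is a stage-k candidate when its adjusted ANOVA p-value is
    below ``adj_p_max`` and its stage-k-vs-control |lfc| (M-scale, from
    the linear engine) exceeds ``lfc_min``.  Lists are ranked by ANOVA
    p-value ascending.
    """
    shared = assoc.index.intersection(stage_lfc.index)
    assoc = assoc.loc[shared]
    stage_lfc = stage_lfc.loc[shared]
    out = {}
    for stage in STAGE_ORDER:
        mask = (assoc["adj_p"] < adj_p_max) & (stage_lfc[stage].abs() > lfc_min)
        sub = assoc.loc[mask].copy()
        sub["lfc"] = stage_lfc.loc[mask, stage]
        out[stage] = sub.sort_values("p")
    return out
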