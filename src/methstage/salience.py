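"""Stage-salient biomarker calling: tiered contrasts and consensus.

A gene is *stage-salient* when it is differentially methylated against
controls in one stage (Tier I: |lfc of M| > 2 and BH-adjusted p < 0.001)
and distinguishable from every other stage (Tier II: the three
inter-stage contrasts involving that stage each at unadjusted p < 0.05),
with a salience margin of |lfc| > 0.4 against the other stages.  Genes
differentially methylated against controls in *all four* stages are
*stage-agnostic*.  Because individual detection engines carry their own
biases, the final call requires agreement by a minimum number of
methods (default 3) on both gene and stage; the direction label (Hyper
when lfc > 0) comes from the stage-vs-control fold-change.

Gene-set enrichment of a called list is assessed by the one-sided
hypergeometric (Fisher exact) upper-tail test with BH adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .linmod import INTERSTAGE_PAIRS, STAGE_ORDER, bh_adjust

__all__ = [
    "TierCriteria",
    "StageSalientCall",
    "tier1_dmgs",
    "tier2_salience",
    "topk_rank",
    "consensus",
    "stage_agnostic",
    "direction",
    "fisher_enrichment",
]

log = logging.getLogger(__name__)


@dataclass
class TierCriteria:
    """Thresholds of the two-tier stage-salience procedure."""

    tier1_lfc_min: float = 2.0  # M-units, stage vs control
    tier1_adjp_max: float = 0.001
    tier2_p_max: float = 0.05  # unadjusted, inter-stage
    salience_margin: float = 0.4  # M-units vs every other stage
    top_k: int = 100
    min_methods: int = 3

    def __post_init__(self):
        if min(self.tier1_lfc_min, self.tier1_adjp_max, self.tier2_p_max, self.salience_margin) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.top_k < 1 or self.min_methods < 1:
            raise ValueError("top_k and min_methods must be >= 1")


@dataclass
class StageSalientCall:
    gene: str
    stage: str
    methods: tuple
    direction: str
    lfc: dict = field(default_factory=dict)  # stage -> lfc vs control
    margins: dict = field(default_factory=dict)  # other stage -> |lfc_k - lfc_j|


def direction(lfc: float) -> str:
    """Hyper- vs hypo-methylation from the sign of the fold-change."""
    if lfc > 0:
        return "Hyper"
    if lfc < 0:
        return "Hypo"
    raise ValueError("direction undefined for lfc = 0")


def tier1_dmgs(contrasts: dict[str, pd.DataFrame], criteria: TierCriteria | None = None) -> dict[str, pd.DataFrame]:
    """First-tier differentially methylated calls, stage vs control.

    ``contrasts`` maps each stage to its stage-vs-control contrast table
    (columns ``lfc``, ``adj_p``).  The stage-k set keeps features with
    |lfc| > tier1_lfc_min and adjusted p < tier1_adjp_max.
    """
    criteria = criteria or TierCriteria()
    missing = [s for s in STAGE_ORDER if s not in contrasts]
    if missing:
        raise ValueError(f"missing stage-vs-control contrasts: {missing}")
    out = {}
    for stage in STAGE_ORDER:
        tab = contrasts[stage]
        mask = (tab["lfc"].abs() > criteria.tier1_lfc_min) & (tab["adj_p"] < criteria.tier1_adjp_max)
        sub = tab.loc[mask].copy()
        sub["direction"] = np.where(sub["lfc"] > 0, "Hyper", "Hypo")
        out[stage] = sub.sort_values("adj_p")
    return out


def tier2_salience(
    gene: str,
    stage: str,
    interstage: dict[tuple[str, str], pd.DataFrame],
    criteria: TierCriteria | None = None,
) -> bool:
    """Second-tier check: the candidate separates from the other stages.

    True iff the three inter-stage contrasts involving ``stage`` each
    show unadjusted p < tier2_p_max for the gene (strict inequality).
    """
    criteria = criteria or TierCriteria()
    relevant = [pair for pair in INTERSTAGE_PAIRS if stage in pair]
    for pair in relevant:
        if pair not in interstage:
            raise ValueError(f"missing inter-stage contrast {pair}")
        tab = interstage[pair]
        if gene not in tab.index:
            return False
        if not tab.loc[gene, "p"] < criteria.tier2_p_max:
            return False
    return True


def topk_rank(table: pd.DataFrame, k: int = 100, gene_of: pd.Series | None = None) -> pd.DataFrame:
    """Rank a per-feature stage list and keep the top k genes.

    Sorts by adjusted p ascending, ties broken by |lfc| descending then
    gene id.  With ``gene_of`` given (probe -> gene), probe-level rows
    are first collapsed to genes keeping each gene's best probe.
    """
    tab = table.copy()
    tab.index = tab.index.rename(None)
    if gene_of is not None:
        tab["_gene"] = gene_of.reindex(tab.index)
        tab = tab.dropna(subset=["_gene"])
    else:
        tab["_gene"] = tab.index
    tab["_abs_lfc"] = tab["lfc"].abs() if "lfc" in tab else 0.0
    sort_p = "adj_p" if "adj_p" in tab else "p"
    tab = tab.sort_values([sort_p, "_abs_lfc", "_gene"], ascending=[True, False, True])
    tab = tab.drop_duplicates(subset="_gene", keep="first")
    out = tab.head(k).drop(columns="_abs_lfc").set_index("_gene")
    out.index.name = "gene"
    return out


def stage_agnostic(tier1: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Genes differentially methylated against control in all four stages.

    Returns per-stage directions; rows with discordant directions across
    stages are flagged (a gene can be hyper- in one stage and hypo- in
    another, which calls for closer inspection).
    """
    sets = [set(tier1[s].index) for s in STAGE_ORDER]
    common = sorted(set.intersection(*sets))
    rows = []
    for g in common:
        dirs = {s: tier1[s].loc[g, "direction"] for s in STAGE_ORDER}
        rows.append({"gene": g, **{f"direction_{s}": d for s, d in dirs.items()}, "concordant": len(set(dirs.values())) == 1})
    return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=[f"direction_{s}" for s in STAGE_ORDER] + ["concordant"]
    )


def consensus(
    method_lists: dict[str, dict[str, pd.DataFrame]],
    interstage: dict[tuple[str, str], pd.DataFrame],
    stage_lfc: pd.DataFrame,
    criteria: TierCriteria | None = None,
) -> list[StageSalientCall]:
    """Consensus stage-salient calls across detection methods.

    Parameters
    ----------
    method_lists : mapping
        method name -> (stage -> ranked gene table indexed by gene), as
        produced by :func:`topk_rank`.
    interstage : mapping
        (stage_a, stage_b) -> inter-stage contrast table from the
        gene-level linear engine (used for the Tier-II gate, since not
        all engines can form inter-stage contrasts).
    stage_lfc : DataFrame
        gene x stage lfc-vs-control matrix from the gene-level linear
        engine (used for direction and salience margins).
    criteria : TierCriteria

    A gene is called salient for stage k when at least ``min_methods``
    methods list it for stage k, it passes Tier II, its salient-stage
    |lfc| exceeds tier1_lfc_min, and its margin |lfc_k - lfc_j| exceeds
    ``salience_margin`` for every other stage j.  A gene qualifying for
    two stages simultaneously is conflicted and rejected.
    """
    criteria = criteria or TierCriteria()
    if len(method_lists) < criteria.min_methods:
        raise ValueError("fewer methods supplied than min_methods")
    candidates: dict[str, list] = {}
    for stage in STAGE_ORDER:
        votes: dict[str, list] = {}
        for method in sorted(method_lists):
            stage_table = method_lists[method].get(stage)
            if stage_table is None:
                continue
            for gene in stage_table.index:
                votes.setdefault(gene, []).append(method)
        for gene, methods in votes.items():
            if len(methods) < criteria.min_methods:
                continue
            if gene not in stage_lfc.index:
                continue
            lfc_k = float(stage_lfc.loc[gene, stage])
            if abs(lfc_k) <= criteria.tier1_lfc_min:
                continue
            if not tier2_salience(gene, stage, interstage, criteria):
                continue
            margins = {
                other: abs(lfc_k - float(stage_lfc.loc[gene, other]))
                for other in STAGE_ORDER
                if other != stage
            }
            if min(margins.values()) <= criteria.salience_margin:
                continue
            candidates.setdefault(gene, []).append(
                StageSalientCall(
                    gene=gene,
                    stage=stage,
                    methods=tuple(sorted(methods)),
                    direction=direction(lfc_k),
                    lfc={s: float(stage_lfc.loc[gene, s]) for s in STAGE_ORDER},
                    margins=margins,
                )
            )
    calls = []
    for gene, gene_calls in sorted(candidates.items()):
        if len(gene_calls) > 1:
            log.warning("gene %s salient in multiple stages (%s); rejected as conflicted", gene, [c.stage for c in gene_calls])
            continue
        calls.append(gene_calls[0])
    calls.sort(key=lambda c: (STAGE_ORDER.index(c.stage), c.gene))
    return calls


def fisher_enrichment(gene_list, gene_sets: dict, universe) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a gene list in gene sets.

    For each set of size K in a universe of size N, with a list of size n
    overlapping the set in k genes, the p-value is the upper tail
    P(X >= k) of Hypergeometric(N, K, n).  BH adjustment across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_list = set(gene_list) & universe
    n = len(gene_list)
    big_n = len(universe)
    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & universe
        big_k = len(members)
        k = len(gene_list & members)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append((set_id, k, big_k, n, big_n, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set_id", "k", "K", "n", "N", "p"]).set_index("set_id")
    out["adj_p"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out
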