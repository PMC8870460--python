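"""End-to-end orchestration: simulate/load -> preprocess -> six
differential-methylation engines -> consensus -> survival.

The six engines mirror the ensemble: (1) probe-level and (2) gene-level
(avereps) linear modelling of M-values, (3) ANOVA association on beta
values, (4) probe-level linear modelling of beta values (DMP mode),
(5) methylation-expression mixture-model driver calling, and (6) linear
modelling of expression estimated from methylation.  Each engine yields
a ranked top-k gene list per stage; the consensus caller combines them
with the Tier-II gate and salience margins from the gene-level linear
engine.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cpg_assoc, methexpr, preprocess, salience, simdata
from .linmod import STAGE_ORDER, StageLinearModel
from .salience import TierCriteria
from . import survival as surv

__all__ = ["PipelineConfig", "run_pipeline", "ALL_ENGINES"]

log = logging.getLogger(__name__)

ALL_ENGINES = ("mvalue", "avereps", "anova", "dmp", "mixture", "exprmodel")


@dataclass
class PipelineConfig:
    """Single configuration for a full run.

    Either ``sim`` (a :class:`~methstage.simdata.SimConfig`) or
    ``input_dir`` (a directory holding the TSV dialects written by
    :func:`~methstage.simdata.write_dataset`) supplies the data.
    """

    sim: simdata.SimConfig | None = None
    input_dir: str | None = None
    criteria: TierCriteria = field(default_factory=TierCriteria)
    engines: tuple = ALL_ENGINES
    sigma_min: float = 1.0
    epsilon: float = 1e-6
    run_survival: bool = True
    maxstat_perms: int = 1000
    minprop: float = 0.1
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.sim is None and self.input_dir is None:
            raise ValueError("either a simulation config or an input directory is required")
        unknown = set(self.engines) - set(ALL_ENGINES)
        if unknown:
            raise ValueError(f"unknown engines: {sorted(unknown)}")
        if len(self.engines) < self.criteria.min_methods:
            raise ValueError(
                f"consensus needs at least {self.criteria.min_methods} engines; {len(self.engines)} enabled"
            )


def _load_inputs(config: PipelineConfig) -> dict:
    if config.sim is not None:
        return simdata.simulate_dataset(config.sim)
    d = Path(config.input_dir)
    data = {
        "beta": preprocess.read_matrix(d / "beta.tsv"),
        "annotation": preprocess.read_probe_annotation(d / "probe_annotation.tsv"),
        "samples": preprocess.read_sample_sheet(d / "samples.tsv"),
        "truth": None,
    }
    expr = d / "expression.tsv"
    data["expression"] = preprocess.read_matrix(expr) if expr.exists() else None
    sv = d / "survival.tsv"
    data["survival"] = pd.read_csv(sv, sep="\t") if sv.exists() else None
    return data


def _stage_lists(results, criteria: TierCriteria, gene_of=None, use_lfc: bool = True):
    """Per-stage ranked top-k gene lists from a fitted linear engine."""
    tables = results.stage_vs_control()
    lists = {}
    for stage, tab in tables.items():
        mask = tab["adj_p"] < criteria.tier1_adjp_max
        if use_lfc:
            mask &= tab["lfc"].abs() > criteria.tier1_lfc_min
        lists[stage] = salience.topk_rank(tab.loc[mask], k=criteria.top_k, gene_of=gene_of)
    return lists


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return all intermediate and
    final results plus a reproducibility manifest."""
    data = _load_inputs(config)
    criteria = config.criteria
    annotation = data["annotation"]
    gene_of = annotation.set_index("probe_id")["gene"]

    # ---- preprocessing -------------------------------------------------
    samples = preprocess.attach_parent_stage(data["samples"])
    beta = data["beta"][samples["sample_id"]]
    beta = preprocess.drop_na_probes(beta)
    m_probe = preprocess.beta_to_m(beta, epsilon=config.epsilon)
    m_probe = preprocess.variance_filter(m_probe, config.sigma_min)
    beta_probe = beta.loc[m_probe.index]
    gene_m = preprocess.variance_filter(
        preprocess.avereps(m_probe, annotation), config.sigma_min
    )
    gene_beta = preprocess.avereps(beta_probe, annotation).loc[gene_m.index]
    counts = {
        "samples_retained": int(len(samples)),
        "probes_complete": int(beta.shape[0]),
        "probes_after_sigma_filter": int(m_probe.shape[0]),
        "genes_after_sigma_filter": int(gene_m.shape[0]),
    }
    log.info("preprocessing: %s", counts)

    cancer_ids = samples.loc[samples["parent_stage"] != "CONTROL", "sample_id"].tolist()
    control_ids = samples.loc[samples["parent_stage"] == "CONTROL", "sample_id"].tolist()
    stage_ids = {
        s: samples.loc[samples["parent_stage"] == s, "sample_id"].tolist() for s in STAGE_ORDER
    }

    # ---- reference gene-level linear engine (always fitted: supplies the
    # Tier-II gate and salience margins for the consensus) ---------------
    gene_results = StageLinearModel(gene_m, samples).fit()
    stage_lfc = pd.DataFrame({s: gene_results.contrast(s)["lfc"] for s in STAGE_ORDER})
    interstage = gene_results.interstage()

    method_lists: dict[str, dict] = {}
    engine_outputs: dict[str, object] = {}

    if "mvalue" in config.engines:
        res = StageLinearModel(m_probe, samples).fit()
        method_lists["mvalue"] = _stage_lists(res, criteria, gene_of=gene_of)
        engine_outputs["mvalue"] = res
    if "avereps" in config.engines:
        method_lists["avereps"] = _stage_lists(gene_results, criteria)
        engine_outputs["avereps"] = gene_results
    if "anova" in config.engines:
        groups = samples["parent_stage"].to_numpy()
        assoc = cpg_assoc.anova_table(gene_beta, groups)
        stage_calls = cpg_assoc.assoc_stage_calls(
            assoc, stage_lfc, adj_p_max=criteria.tier1_adjp_max, lfc_min=criteria.tier1_lfc_min
        )
        method_lists["anova"] = {
            s: salience.topk_rank(tab.assign(adj_p=tab["adj_p"]), k=criteria.top_k)
            for s, tab in stage_calls.items()
        }
        engine_outputs["anova"] = assoc
    if "dmp" in config.engines:
        res = StageLinearModel(beta_probe, samples).fit()
        # beta-scale fold-changes live in (-1, 1); the M-scale lfc gate does
        # not transfer, so DMP lists are screened on adjusted p alone
        method_lists["dmp"] = _stage_lists(res, criteria, gene_of=gene_of, use_lfc=False)
        engine_outputs["dmp"] = res
    if "mixture" in config.engines and data.get("expression") is not None:
        corr = methexpr.meth_expr_correlation(gene_beta[cancer_ids], data["expression"][cancer_ids])
        driver_tables = {}
        mm_lists = {}
        for i, stage in enumerate(STAGE_ORDER):
            calls = methexpr.driver_calls(
                stage,
                gene_m,
                corr,
                stage_ids[stage],
                control_ids,
                seed=(config.seed + 1000 * (i + 1)) % (2**31 - 1),
            )
            driver_tables[stage] = calls
            drivers = calls.loc[calls["driver"]].sort_values("adj_p").drop_duplicates("gene")
            mm_lists[stage] = drivers.set_index("gene").head(criteria.top_k)
        method_lists["mixture"] = mm_lists
        engine_outputs["mixture"] = {"correlations": corr, "drivers": driver_tables}
    if "exprmodel" in config.engines and data.get("expression") is not None:
        est = methexpr.estimate_expression(gene_beta, data["expression"], gene_beta)
        res = StageLinearModel(est.predictions, samples).fit()
        # estimated-expression scale is arbitrary: screen on adjusted p
        method_lists["exprmodel"] = _stage_lists(res, criteria, use_lfc=False)
        engine_outputs["exprmodel"] = est

    # ---- consensus + stage-agnostic ------------------------------------
    tier1 = salience.tier1_dmgs(
        {s: gene_results.contrast(s) for s in STAGE_ORDER}, criteria
    )
    agnostic = salience.stage_agnostic(tier1)
    calls = salience.consensus(method_lists, interstage, stage_lfc, criteria)

    # ---- survival -------------------------------------------------------
    survival_results = None
    if config.run_survival and data.get("survival") is not None and len(calls):
        survival_results = _survival_evaluation(calls, gene_m, data["survival"], config)

    result = {
        "counts": counts,
        "samples": samples,
        "gene_m": gene_m,
        "gene_beta": gene_beta,
        "stage_lfc": stage_lfc,
        "method_lists": method_lists,
        "engines": engine_outputs,
        "tier1": tier1,
        "stage_agnostic": agnostic,
        "consensus": calls,
        "survival": survival_results,
    }
    if data.get("truth") is not None:
        result["recovery"] = recovery_report(calls, agnostic, data["truth"])
    result["manifest"] = _manifest(config, result)
    if config.out_dir:
        _write_outputs(result, config.out_dir)
    return result


def _survival_evaluation(calls, gene_m, survival_df, config: PipelineConfig):
    """Univariate Cox per consensus gene, then early/late-stage panels."""
    ids = [s for s in survival_df["sample_id"] if s in gene_m.columns]
    sub = survival_df.set_index("sample_id").loc[ids]
    times = sub["time"].to_numpy(dtype=float)
    events = sub["event"].to_numpy(dtype=int)
    x = gene_m[ids].T  # samples x genes
    univariate = []
    for call in calls:
        g = call.gene
        if g not in x.columns or x[g].nunique() <= 1:
            continue
        try:
            fit = surv.cox_fit(x[[g]], times, events)
        except (ValueError, RuntimeError) as exc:
            log.warning("univariate Cox failed for %s: %s", g, exc)
            continue
        univariate.append(
            {
                "gene": g,
                "stage": call.stage,
                "coef": float(fit.coefficients.iloc[0]),
                "hr": float(np.exp(fit.coefficients.iloc[0])),
                "p": float(fit.p.iloc[0]),
            }
        )
    uni = pd.DataFrame(univariate)
    panels = {}
    groups = {
        "early": [c.gene for c in calls if c.stage in ("I", "II")],
        "late": [c.gene for c in calls if c.stage in ("III", "IV")],
    }
    for name, genes in groups.items():
        genes = [g for g in genes if g in x.columns]
        if len(genes) < 1:
            continue
        try:
            panels[name] = surv.evaluate_panel(
                name,
                genes,
                x,
                times,
                events,
                minprop=config.minprop,
                n_perm=config.maxstat_perms,
                seed=(config.seed + 77) % (2**31 - 1),
            )
        except (ValueError, RuntimeError) as exc:
            log.warning("panel %s evaluation failed: %s", name, exc)
    return {"univariate": uni, "panels": panels}


def recovery_report(calls, agnostic: pd.DataFrame, truth: simdata.GroundTruth) -> dict:
    """Score consensus calls against the planted ground truth."""
    called = {c.gene: c for c in calls}
    planted = truth.stage_salient
    correct = sum(
        1
        for g, (stage, direction) in planted.items()
        if g in called and called[g].stage == stage
    )
    direction_ok = sum(
        1
        for g, (stage, direction) in planted.items()
        if g in called and called[g].stage == stage and called[g].direction == direction
    )
    false_calls = [g for g in called if g not in planted]
    agnostic_planted = set(truth.stage_agnostic)
    agnostic_found = agnostic_planted & set(agnostic.index)
    return {
        "n_planted_salient": len(planted),
        "n_called": len(called),
        "n_correct_stage": correct,
        "n_correct_direction": direction_ok,
        "recall": correct / len(planted) if planted else float("nan"),
        "false_calls": false_calls,
        "n_planted_agnostic": len(agnostic_planted),
        "agnostic_recall": len(agnostic_found) / len(agnostic_planted) if agnostic_planted else float("nan"),
    }


def _manifest(config: PipelineConfig, result: dict) -> dict:
    def _hash(obj) -> str:
        if isinstance(obj, pd.DataFrame):
            payload = obj.to_csv().encode()
        else:
            payload = json.dumps(obj, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    return {
        "seed": config.seed,
        "engines": list(config.engines),
        "criteria": vars(config.criteria),
        "counts": result["counts"],
        "hashes": {
            "gene_m": _hash(result["gene_m"]),
            "stage_lfc": _hash(result["stage_lfc"]),
            "consensus": _hash([(c.gene, c.stage, c.direction) for c in result["consensus"]]),
        },
    }


def _write_outputs(result: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "gene": c.gene,
            "stage": c.stage,
            "direction": c.direction,
            "methods": ",".join(c.methods),
            "min_margin": min(c.margins.values()),
        }
        for c in result["consensus"]
    ]
    pd.DataFrame(rows).to_csv(out / "consensus_calls.tsv", sep="\t", index=False)
    result["stage_agnostic"].to_csv(out / "stage_agnostic.tsv", sep="\t")
    (out / "manifest.json").write_text(json.dumps(result["manifest"], indent=2, sort_keys=True))
    if result.get("survival") and len(result["survival"]["univariate"]):
        result["survival"]["univariate"].to_csv(out / "survival_univariate.tsv", sep="\t", index=False)
    if "recovery" in result:
        (out / "recovery.json").write_text(json.dumps(result["recovery"], indent=2, sort_keys=True))
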