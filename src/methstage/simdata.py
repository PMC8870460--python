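"""Synthetic methylation / expression / clinical data with planted truth.

The generator emulates the statistical structure the downstream analysis
assumes for a 27k-style methylation array study of staged tumors with
normal controls:

* per-probe beta values drawn from Beta distributions whose means come
  from two pools (a hypomethylated and a hypermethylated pool), the
  bimodal marginal typical of array data;
* several probes per gene;
* planted *stage-salient* genes: all probes of the gene shifted by
  ``delta_M`` on the M (logit2) scale in the target stage only -- the
  scale on which all analysis thresholds are defined;
* planted *stage-agnostic* genes shifted in all four stages;
* expression negatively coupled to methylation for planted (driver)
  genes: expression = intercept + slope * mean(beta) + Gaussian noise;
* missing entries injected uniformly at random;
* clinical substage labels drawn with a realistic substage composition,
  and exponential survival whose hazard is log-linear in the planted
  prognostic genes' M-values, with independent exponential censoring
  whose rate is solved to hit the target censoring fraction.

All outputs are deterministic functions of the configuration, including
its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .preprocess import beta_to_m, m_to_beta

__all__ = ["SimConfig", "GroundTruth", "simulate_methylation", "simulate_expression", "simulate_clinical_survival", "simulate_dataset", "write_dataset"]

#: Substage composition used when drawing raw stage labels, patterned on
#: the composition of a typical colorectal 27k cohort: parent-stage-only
#: labels plus lettered substages in roughly the observed proportions.
SUBSTAGE_WEIGHTS = {
    "I": {"I": 1.0},
    "II": {"II": 17 / 86, "IIa": 64 / 86, "IIb": 5 / 86},
    "III": {"III": 16 / 60, "IIIa": 3 / 60, "IIIb": 21 / 60, "IIIc": 20 / 60},
    "IV": {"IV": 35 / 36, "IVa": 1 / 36},
}

_STAGES = ("I", "II", "III", "IV")


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    Planted lists:

    * ``planted_stage_salient``: (gene index, stage, delta_M) triples --
      sign of delta_M sets hyper (+) vs hypo (-);
    * ``planted_stage_agnostic``: (gene index, delta_M) pairs, shifted
      in all four stages;
    * ``planted_prognostic``: (gene index, log-hazard coefficient).
    """

    n_controls: int = 40
    n_per_stage: int = 40
    n_genes: int = 2000
    probes_per_gene: tuple[int, int] = (1, 4)
    # (mean_low, mean_high, concentration_low, concentration_high) per pool
    hypo_pool: tuple[float, float, float, float] = (0.08, 0.35, 4.0, 10.0)
    hyper_pool: tuple[float, float, float, float] = (0.65, 0.92, 4.0, 10.0)
    hyper_fraction: float = 0.4  # fraction of probes from the hyper pool
    planted_stage_salient: list = field(default_factory=list)
    planted_stage_agnostic: list = field(default_factory=list)
    planted_prognostic: list = field(default_factory=list)
    expr_slope: float = -10.0
    expr_noise_sd: float = 1.0
    missing_rate: float = 0.0
    censor_rate: float = 0.2
    baseline_hazard: float = 1.0 / 1000.0  # per day
    max_abs_delta_m: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_controls, self.n_per_stage, self.n_genes) <= 0:
            raise ValueError("all counts must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        salient_genes = {g for g, *_ in self.planted_stage_salient}
        agnostic_genes = {g for g, *_ in self.planted_stage_agnostic}
        if salient_genes & agnostic_genes:
            raise ValueError("planted genes must be distinct across salient and agnostic lists")
        deltas = [d for _, _, d in self.planted_stage_salient] + [d for _, d in self.planted_stage_agnostic]
        for d in deltas:
            if abs(d) > self.max_abs_delta_m:
                raise ValueError(
                    f"planted shift delta_M={d} would push beta values into the clipping region "
                    f"(|delta_M| <= {self.max_abs_delta_m})"
                )


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery scoring."""

    stage_salient: dict  # gene -> (stage, direction)
    stage_agnostic: dict  # gene -> direction
    prognostic: dict  # gene -> log-hazard coefficient
    baseline_means: pd.Series  # probe -> baseline mean beta

    def to_json(self) -> str:
        return json.dumps(
            {
                "stage_salient": {g: list(v) for g, v in self.stage_salient.items()},
                "stage_agnostic": dict(self.stage_agnostic),
                "prognostic": dict(self.prognostic),
            },
            indent=2,
            sort_keys=True,
        )


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def _sample_frame(config: SimConfig):
    """Sample ids and parent stages in fixed column order."""
    ids, stages = [], []
    for i in range(config.n_controls):
        ids.append(f"CTRL{i:04d}")
        stages.append("CONTROL")
    for stage in _STAGES:
        for i in range(config.n_per_stage):
            ids.append(f"S{stage}_{i:04d}")
            stages.append(stage)
    return ids, stages


def simulate_methylation(config: SimConfig):
    """Generate the beta matrix, probe annotation and ground truth.

    Returns ``(beta, annotation, truth)``: beta is probe x sample with
    NaN for injected missing entries; annotation has probe_id, gene and
    distance_to_TSS columns.
    """
    rng = np.random.default_rng(config.seed)
    sample_ids, stages = _sample_frame(config)
    stages = np.array(stages)
    n_samples = len(sample_ids)

    # probes per gene and annotation
    lo, hi = config.probes_per_gene
    probes_per_gene = rng.integers(lo, hi + 1, size=config.n_genes)
    genes = [_gene_name(i) for i in range(config.n_genes)]
    probe_ids, probe_gene = [], []
    for g, npb in zip(genes, probes_per_gene):
        for j in range(npb):
            probe_ids.append(f"cg_{g}_{j}")
            probe_gene.append(g)
    n_probes = len(probe_ids)
    annotation = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene": probe_gene,
            "distance_to_TSS": rng.integers(0, 1500, size=n_probes),
        }
    )

    # baseline Beta shapes from the bimodal pools
    from_hyper = rng.random(n_probes) < config.hyper_fraction
    means = np.where(
        from_hyper,
        rng.uniform(config.hyper_pool[0], config.hyper_pool[1], size=n_probes),
        rng.uniform(config.hypo_pool[0], config.hypo_pool[1], size=n_probes),
    )
    conc = np.where(
        from_hyper,
        rng.uniform(config.hyper_pool[2], config.hyper_pool[3], size=n_probes),
        rng.uniform(config.hypo_pool[2], config.hypo_pool[3], size=n_probes),
    )
    a = means * conc
    b = (1.0 - means) * conc
    beta_vals = rng.beta(a[:, None], b[:, None], size=(n_probes, n_samples))
    eps = 1e-9
    beta_vals = np.clip(beta_vals, eps, 1 - eps)

    # plant effects additively in M space, then back-transform
    shift = np.zeros((n_probes, n_samples))
    probe_gene_arr = np.array(probe_gene)
    truth_salient, truth_agnostic = {}, {}
    for gene_i, stage, delta in config.planted_stage_salient:
        gname = _gene_name(gene_i) if isinstance(gene_i, (int, np.integer)) else gene_i
        rows = probe_gene_arr == gname
        cols = stages == stage
        shift[np.ix_(rows, cols)] += delta
        truth_salient[gname] = (stage, "Hyper" if delta > 0 else "Hypo")
    for gene_i, delta in config.planted_stage_agnostic:
        gname = _gene_name(gene_i) if isinstance(gene_i, (int, np.integer)) else gene_i
        rows = probe_gene_arr == gname
        cols = stages != "CONTROL"
        shift[np.ix_(rows, cols)] += delta
        truth_agnostic[gname] = "Hyper" if delta > 0 else "Hypo"
    if shift.any():
        m = beta_to_m(beta_vals, epsilon=eps) + shift
        beta_vals = m_to_beta(m)
        beta_vals = np.clip(beta_vals, eps, 1 - eps)

    if config.missing_rate > 0:
        mask = rng.random((n_probes, n_samples)) < config.missing_rate
        beta_vals = np.where(mask, np.nan, beta_vals)

    beta = pd.DataFrame(beta_vals, index=probe_ids, columns=sample_ids)
    truth = GroundTruth(
        stage_salient=truth_salient,
        stage_agnostic=truth_agnostic,
        prognostic={
            (_gene_name(g) if isinstance(g, (int, np.integer)) else g): float(c)
            for g, c in config.planted_prognostic
        },
        baseline_means=pd.Series(means, index=probe_ids),
    )
    return beta, annotation, truth


def _gene_mean_beta(beta: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    gene_of = annotation.set_index("probe_id")["gene"]
    return beta.groupby(gene_of.reindex(beta.index).to_numpy()).mean()


def simulate_expression(beta: pd.DataFrame, truth: GroundTruth, config: SimConfig, annotation: pd.DataFrame) -> pd.DataFrame:
    """Paired expression matrix (gene x sample).

    Planted (driver) genes: expression is a noisy negative-slope linear
    function of the gene's mean beta; all other genes are independent
    Gaussian noise around a gene-specific baseline.
    """
    rng = np.random.default_rng(config.seed + 1)
    gene_beta = _gene_mean_beta(beta, annotation)  # groupby mean skips NaN
    drivers = set(truth.stage_salient) | set(truth.stage_agnostic) | set(truth.prognostic)
    missing = drivers - set(gene_beta.index)
    if missing:
        raise ValueError(f"planted genes absent from the beta annotation: {sorted(missing)[:5]}")
    n_genes, n_samples = gene_beta.shape
    base = rng.normal(8.0, 1.0, size=n_genes)
    expr = base[:, None] + rng.normal(0.0, config.expr_noise_sd, size=(n_genes, n_samples))
    is_driver = gene_beta.index.isin(drivers)
    expr[is_driver] = (
        base[is_driver, None]
        + config.expr_slope * gene_beta.to_numpy()[is_driver]
        + rng.normal(0.0, config.expr_noise_sd, size=(is_driver.sum(), n_samples))
    )
    return pd.DataFrame(expr, index=gene_beta.index, columns=gene_beta.columns)


def _solve_censor_rate(event_rates: np.ndarray, target: float) -> float:
    """Censoring rate c with mean_i c/(c + lambda_i) = target."""
    if target == 0:
        return 0.0

    def gap(c):
        return float(np.mean(c / (c + event_rates))) - target

    hi = event_rates.max()
    while gap(hi) < 0:
        hi *= 10
        if hi > 1e12:
            break
    return float(optimize.brentq(gap, 1e-15, hi))


def simulate_clinical_survival(truth: GroundTruth, beta: pd.DataFrame, config: SimConfig, annotation: pd.DataFrame):
    """Sample sheet with substage labels plus survival records.

    Event times are exponential with per-sample hazard
    ``baseline_hazard * exp(sum_g coef_g * M_g)`` over the planted
    prognostic genes; censoring times are independent exponentials whose
    rate is solved so the expected censored fraction equals
    ``censor_rate``.  Controls receive no survival record.
    """
    rng = np.random.default_rng(config.seed + 2)
    sample_ids, parent = _sample_frame(config)
    parent = np.array(parent)
    raw = []
    for st in parent:
        if st == "CONTROL":
            raw.append("CONTROL")
        else:
            labels = list(SUBSTAGE_WEIGHTS[st])
            probs = np.array([SUBSTAGE_WEIGHTS[st][l] for l in labels])
            raw.append(labels[rng.choice(len(labels), p=probs / probs.sum())])
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "pathologic_stage": raw,
            "batch": rng.choice(["batch1", "batch2"], size=len(sample_ids)),
        }
    )

    cases = parent != "CONTROL"
    case_ids = np.array(sample_ids)[cases]
    log_hr = np.zeros(cases.sum())
    if truth.prognostic:
        gene_beta = _gene_mean_beta(beta, annotation)
        sub = gene_beta.loc[list(truth.prognostic), case_ids]
        sub = sub.apply(lambda row: row.fillna(row.mean()), axis=1)  # rare fully-missing entries
        m = beta_to_m(np.clip(sub.to_numpy(), 1e-9, 1 - 1e-9))
        coefs = np.array([truth.prognostic[g] for g in truth.prognostic])
        log_hr = coefs @ m
    rates = config.baseline_hazard * np.exp(log_hr)
    event_t = rng.exponential(1.0 / rates)
    c_rate = _solve_censor_rate(rates, config.censor_rate)
    if c_rate > 0:
        censor_t = rng.exponential(1.0 / c_rate, size=len(event_t))
        time = np.minimum(event_t, censor_t)
        event = (event_t <= censor_t).astype(int)
    else:
        time, event = event_t, np.ones(len(event_t), dtype=int)
    surv = pd.DataFrame({"sample_id": case_ids, "time": time, "event": event})
    return sheet, surv


def simulate_dataset(config: SimConfig):
    """Full synthetic bundle: beta, annotation, expression, sample sheet,
    survival and ground truth (all deterministic in the config)."""
    beta, annotation, truth = simulate_methylation(config)
    expr = simulate_expression(beta, truth, config, annotation)
    sheet, surv = simulate_clinical_survival(truth, beta, config, annotation)
    return {
        "beta": beta,
        "annotation": annotation,
        "expression": expr,
        "samples": sheet,
        "survival": surv,
        "truth": truth,
    }


def write_dataset(data: dict, out_dir) -> dict:
    """Write the simulated bundle as the package's TSV/JSON dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    data["beta"].to_csv(out / "beta.tsv", sep="\t", na_rep="na")
    data["annotation"].to_csv(out / "probe_annotation.tsv", sep="\t", index=False)
    data["expression"].to_csv(out / "expression.tsv", sep="\t")
    data["samples"].to_csv(out / "samples.tsv", sep="\t", index=False)
    data["survival"].to_csv(out / "survival.tsv", sep="\t", index=False)
    (out / "ground_truth.json").write_text(data["truth"].to_json())
    for name in ["beta.tsv", "probe_annotation.tsv", "expression.tsv", "samples.tsv", "survival.tsv", "ground_truth.json"]:
        paths[name] = str(out / name)
    return paths
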