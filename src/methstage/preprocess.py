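"""Input handling and preprocessing for methylation array matrices.

The analysis operates on two representations of CpG methylation: the
``beta`` value, the fraction methylated at a probe (bounded in (0, 1)),
and the ``M`` value, its base-2 logit, which is unbounded and closer to
homoscedastic -- the scale on which linear modelling is performed.

Functions here read the wide TSV dialects used throughout the package
(probes/genes as rows, samples as columns, ``na`` for missing), convert
beta to M, discard probes with missing entries, drop low-variability
features, aggregate probe-level values to gene level, map pathologic
substage labels onto parent AJCC stages, and compute the batch-effect
and PCA quality-control diagnostics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "beta_to_m",
    "m_to_beta",
    "drop_na_probes",
    "variance_filter",
    "avereps",
    "map_stage",
    "classify_promoter_region",
    "dsc",
    "pca_qc",
    "read_matrix",
    "write_matrix",
    "read_sample_sheet",
    "read_probe_annotation",
    "validate_inputs",
    "STAGE_LABELS",
    "PARENT_STAGES",
    "DISCARD",
]

#: Parent-stage vocabulary after AJCC mapping.
PARENT_STAGES = ("CONTROL", "I", "II", "III", "IV")

#: Sentinel returned by :func:`map_stage` for samples with unknown stage.
DISCARD = "DISCARD"

#: Raw pathologic substage vocabulary -> parent stage.  ``NA`` means the
#: stage attribute is unavailable and the sample is discarded.
STAGE_LABELS = {
    "CONTROL": "CONTROL",
    "I": "I",
    "II": "II",
    "IIa": "II",
    "IIb": "II",
    "III": "III",
    "IIIa": "III",
    "IIIb": "III",
    "IIIc": "III",
    "IV": "IV",
    "IVa": "IV",
    "NA": DISCARD,
}


def beta_to_m(beta, epsilon: float = 1e-6):
    """Convert beta values to M values, ``M = log2(beta / (1 - beta))``.

    Beta values are clipped into ``[epsilon, 1 - epsilon]`` first so that
    boundary values produce finite M values.

    Parameters
    ----------
    beta : DataFrame or ndarray
        Beta values in (0, 1); must contain no missing entries (call
        :func:`drop_na_probes` first).
    epsilon : float
        Clipping bound keeping the logit finite.

    Returns
    -------
    Same type as input, with M values.
    """
    values = beta.to_numpy(dtype=float) if isinstance(beta, pd.DataFrame) else np.asarray(beta, dtype=float)
    if np.isnan(values).any():
        raise ValueError("beta matrix contains missing values; drop NA probes before transforming")
    clipped = np.clip(values, epsilon, 1.0 - epsilon)
    m = np.log2(clipped / (1.0 - clipped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: ``beta = 2^M / (1 + 2^M)``."""
    values = m.to_numpy(dtype=float) if isinstance(m, pd.DataFrame) else np.asarray(m, dtype=float)
    beta = 1.0 / (1.0 + np.exp2(-values))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    return beta


def drop_na_probes(beta: pd.DataFrame) -> pd.DataFrame:
    """Discard probes (rows) with one or more missing entries.

    Row order of the retained probes is preserved.  Raises ``ValueError``
    if no probe survives.
    """
    keep = beta.notna().all(axis=1)
    out = beta.loc[keep]
    if out.shape[0] == 0:
        raise ValueError("all probes contain missing values; nothing left to analyse")
    return out


def variance_filter(m: pd.DataFrame, sigma_min: float = 1.0) -> pd.DataFrame:
    """Drop features showing little change in methylation across samples.

    A feature is retained when its sample standard deviation (ddof=1)
    across all samples is ``>= sigma_min``; i.e. features with
    ``sigma < sigma_min`` are removed (strict inequality, so a feature
    sitting exactly at the threshold survives).
    """
    sd = m.std(axis=1, ddof=1)
    return m.loc[sd >= sigma_min]


def avereps(m: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a probe-level matrix to gene level by averaging probes.

    Each gene row is the arithmetic mean of its probes' values per sample.
    Probes without an annotation entry are dropped.

    Parameters
    ----------
    m : DataFrame
        Probe x sample matrix.
    annotation : DataFrame
        Must contain columns ``probe_id`` and ``gene``.
    """
    if annotation.empty:
        raise ValueError("empty probe annotation")
    gene_of = annotation.set_index("probe_id")["gene"]
    annotated = m.index.intersection(gene_of.index)
    dropped = m.shape[0] - len(annotated)
    if dropped:
        # unannotated probes carry no gene assignment and cannot be aggregated
        m = m.loc[annotated]
    genes = gene_of.loc[m.index]
    out = m.groupby(genes.to_numpy()).mean()
    out.index.name = "gene"
    return out


def map_stage(raw_label: str) -> str:
    """Map a raw pathologic substage label to its AJCC parent stage.

    Substages aggregate to the parent stage (IIa, IIb -> II; IIIa, IIIb,
    IIIc -> III; IVa -> IV).  ``NA`` maps to the :data:`DISCARD` sentinel;
    labels outside the vocabulary raise ``ValueError``.
    """
    label = str(raw_label).strip()
    if label not in STAGE_LABELS:
        raise ValueError(f"unrecognized pathologic stage label: {raw_label!r}")
    return STAGE_LABELS[label]


def classify_promoter_region(distance_to_tss: int, core_max: int = 100, proximal_max: int = 1000) -> str:
    """Classify a CpG by distance (bp) to the transcription start site.

    Core promoter when within ``core_max`` bp of the TSS, proximal
    promoter when within ``proximal_max`` bp, otherwise distal/other.
    """
    d = int(distance_to_tss)
    if d < 0:
        raise ValueError("distance to TSS must be non-negative")
    if d <= core_max:
        return "Core"
    if d <= proximal_max:
        return "Proximal"
    return "Distal/other"


def dsc(m: pd.DataFrame, batches) -> float:
    """Dispersion Separability Criterion for batch-effect assessment.

    Ratio of between-batch dispersion (size-weighted mean Euclidean
    distance of batch centroids from the grand centroid) to within-batch
    dispersion (mean distance of samples from their own batch centroid).
    Values well below 1 (the screening convention is < 0.3) indicate
    negligible batch structure.

    Parameters
    ----------
    m : DataFrame
        Feature x sample matrix.
    batches : sequence
        Batch label per sample (same order as columns).
    """
    batches = np.asarray(batches)
    if len(batches) != m.shape[1]:
        raise ValueError("one batch label per sample required")
    labels = pd.unique(batches)
    if len(labels) < 2:
        raise ValueError("DSC requires at least two batches")
    x = m.to_numpy(dtype=float).T  # samples x features
    grand = x.mean(axis=0)
    between = 0.0
    within = 0.0
    n = x.shape[0]
    for lab in labels:
        mask = batches == lab
        if mask.sum() < 2:
            raise ValueError(f"batch {lab!r} has fewer than two samples")
        sub = x[mask]
        centroid = sub.mean(axis=0)
        between += mask.sum() * np.linalg.norm(centroid - grand)
        within += np.linalg.norm(sub - centroid, axis=1).sum()
    return float((between / n) / (within / n))


def pca_qc(m: pd.DataFrame, features=None):
    """Top-two principal-component coordinates of the samples.

    Centered SVD on the (optionally feature-subset) matrix.  Returns a
    DataFrame of per-sample PC1/PC2 coordinates and the fraction of
    variance each component explains.
    """
    sub = m.loc[features] if features is not None else m
    if sub.shape[0] < 2 or sub.shape[1] < 3:
        raise ValueError("PCA QC needs at least 2 features and 3 samples")
    x = sub.to_numpy(dtype=float).T
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    if (s > 1e-12).sum() < 2:
        raise ValueError("matrix rank < 2; PCA coordinates undefined")
    coords = u[:, :2] * s[:2]
    var_frac = (s[:2] ** 2) / (s**2).sum()
    frame = pd.DataFrame(coords, index=sub.columns, columns=["PC1", "PC2"])
    return frame, var_frac


# ---------------------------------------------------------------------------
# TSV I/O (wide matrices, sample sheets, probe annotation)
# ---------------------------------------------------------------------------

_NA_TOKENS = ["na", "NA", "NaN", ""]


def read_matrix(path) -> pd.DataFrame:
    """Read a wide feature x sample TSV (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA_TOKENS, keep_default_na=False)
    if df.index.duplicated().any():
        raise ValueError("duplicated feature identifiers in matrix")
    if df.columns.duplicated().any():
        raise ValueError("duplicated sample identifiers in matrix")
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="na")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet TSV (sample_id, pathologic_stage, batch, ...)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns or "pathologic_stage" not in df.columns:
        raise ValueError("sample sheet needs 'sample_id' and 'pathologic_stage' columns")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicated sample identifiers in sample sheet")
    return df


def read_probe_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene": str})
    if not {"probe_id", "gene"}.issubset(df.columns):
        raise ValueError("probe annotation needs 'probe_id' and 'gene' columns")
    return df


def attach_parent_stage(samples: pd.DataFrame) -> pd.DataFrame:
    """Map raw labels, drop unknown-stage samples, add ``parent_stage``."""
    mapped = samples["pathologic_stage"].map(map_stage)
    out = samples.loc[mapped != DISCARD].copy()
    out["parent_stage"] = mapped[mapped != DISCARD]
    return out


def validate_inputs(beta: pd.DataFrame, samples: pd.DataFrame, annotation: pd.DataFrame | None = None) -> list[str]:
    """Fail-fast validation of a matrix / sample-sheet / annotation trio.

    Returns an itemized list of violations (empty when clean): beta range
    errors (naming probe and sample), matrix/sheet sample mismatches, and
    unannotated probe counts.
    """
    errors: list[str] = []
    vals = beta.to_numpy(dtype=float)
    bad = np.argwhere((vals <= 0) | (vals >= 1))
    for i, j in bad[:20]:
        if not np.isnan(vals[i, j]):
            errors.append(
                f"beta value {vals[i, j]:g} out of (0,1) at probe {beta.index[i]!r}, sample {beta.columns[j]!r}"
            )
    sheet_ids = set(samples["sample_id"])
    for sid in beta.columns:
        if sid not in sheet_ids:
            errors.append(f"sample {sid!r} present in matrix but missing from sample sheet")
    for sid in sheet_ids - set(beta.columns):
        errors.append(f"sample {sid!r} present in sample sheet but missing from matrix")
    if annotation is not None:
        missing = beta.index.difference(annotation["probe_id"])
        if len(missing):
            errors.append(f"{len(missing)} probes lack annotation (first: {missing[0]!r})")
    return errors
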