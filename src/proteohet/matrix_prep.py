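"""Deterministic preparation of the quantitative matrices.

Proteomic label-free intensities are log2-transformed, low-intensity
artifacts (log2 < 10) removed, median-scale normalised per replicate,
replicate-averaged, filtered for missingness and completed with a
left-censored "minimal value" (MinProb) imputer. RNA-seq support covers
the three-metric quality classification, replicate selection, RPKM/TPM
normalisation and the raw-count transcript filter, plus the tumour-content
sample filter used by the comparative analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PrepParams:
    artifact_log2_floor: float = 10.0
    max_missing_frac: float = 0.10
    impute_q: float = 0.02
    impute_tune_sigma: float = 1.0
    tumour_content_min: float = 60.0
    seed: int = 0


@dataclass(frozen=True)
class RnaQcThresholds:
    """Good/poor bounds for (mRNA %, million assigned reads, assigned %)."""

    good_mrna_pct: float = 76.84
    good_m_reads: float = 3.6
    good_assigned_pct: float = 48.3
    poor_mrna_pct: float = 60.0
    poor_m_reads: float = 2.3
    poor_assigned_pct: float = 38.9

    def __post_init__(self):
        if not (
            self.good_mrna_pct > self.poor_mrna_pct
            and self.good_m_reads > self.poor_m_reads
            and self.good_assigned_pct > self.poor_assigned_pct
        ):
            raise ValueError("good bounds must exceed poor bounds componentwise")


def preprocess(
    raw: pd.DataFrame,
    replicate_map: Mapping[str, str],
    params: PrepParams = PrepParams(),
) -> pd.DataFrame:
    """Proteomic post-processing: log2, artifact floor, median scaling, averaging.

    ``raw`` is proteins x replicate columns of raw (linear) intensities, NaN
    where not quantified; ``replicate_map`` maps each replicate column to its
    sample. Pipeline order: log2-transform; set cells with log2 intensity
    below the artifact floor to missing; centre each replicate to its median
    and add back the global median (computed over all observed values before
    centring); average the replicates of each sample ignoring missing values.
    """
    unmapped = [c for c in raw.columns if c not in replicate_map]
    if unmapped:
        raise KeyError(f"replicates missing from replicate_map: {unmapped}")
    vals = raw.to_numpy(dtype=float)
    if np.any(vals[~np.isnan(vals)] <= 0):
        raise ValueError("non-positive raw intensity encountered")
    log2 = np.log2(vals)
    log2[log2 < params.artifact_log2_floor] = np.nan
    mat = pd.DataFrame(log2, index=raw.index, columns=raw.columns)

    global_median = float(np.nanmedian(mat.to_numpy()))
    mat = mat - mat.median(axis=0, skipna=True) + global_median

    samples: dict[str, list[str]] = {}
    for rep, sample in replicate_map.items():
        if rep in mat.columns:
            samples.setdefault(sample, []).append(rep)
    out = pd.DataFrame(
        {s: mat[cols].mean(axis=1, skipna=True) for s, cols in samples.items()},
        index=mat.index,
    )
    return out


def filter_missingness(matrix: pd.DataFrame, max_missing_frac: float = 0.10) -> pd.DataFrame:
    """Keep proteins with at most ``max_missing_frac`` missing across samples."""
    frac = matrix.isna().mean(axis=1)
    return matrix.loc[frac <= max_missing_frac]


def impute_minprob(
    matrix: pd.DataFrame,
    q: float = 0.02,
    tune_sigma: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Left-censored stochastic minimal-value imputation.

    Missing cells of sample ``s`` are drawn from Normal(mu_s, sigma), where
    mu_s is the ``q``-quantile of that sample's observed values and sigma is
    ``tune_sigma`` times the median (over proteins) of the per-protein
    observed standard deviation. Observed cells are untouched; the draw is
    deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    n_obs = out.notna().sum(axis=0)
    short = n_obs[n_obs < 3]
    if len(short):
        raise ValueError(f"samples with <3 observed values: {list(short.index)}")

    row_sd = out.std(axis=1, skipna=True, ddof=1)
    sigma = tune_sigma * float(row_sd.dropna().median())
    if not math.isfinite(sigma) or sigma <= 0:
        raise ValueError("cannot derive imputation sigma from observed values")

    for col in out.columns:
        miss = out[col].isna()
        if not miss.any():
            continue
        mu = float(out.loc[~miss, col].quantile(q))
        out.loc[miss, col] = rng.normal(mu, sigma, size=int(miss.sum()))
    return out


def _metric_class(value: float, good: float, poor: float) -> str:
    if value > good:
        return "good"
    if value <= poor:
        return "poor"
    return "medium"


def classify_rnaseq_quality(
    metrics: pd.DataFrame, thresholds: RnaQcThresholds = RnaQcThresholds()
) -> pd.Series:
    """Per-sample RNA-seq quality from (mrna_pct, m_reads, assigned_pct).

    Each metric is classified good/medium/poor against its thresholds; a
    sample is good iff all three metrics are good, poor iff all three are
    poor, else medium.
    """
    required = ["mrna_pct", "m_reads", "assigned_pct"]
    missing = [c for c in required if c not in metrics.columns]
    if missing or metrics[required].isna().any().any():
        raise ValueError(f"missing RNA QC metrics: {missing or 'NaN values present'}")
    labels = []
    for _, row in metrics.iterrows():
        per_metric = [
            _metric_class(row["mrna_pct"], thresholds.good_mrna_pct, thresholds.poor_mrna_pct),
            _metric_class(row["m_reads"], thresholds.good_m_reads, thresholds.poor_m_reads),
            _metric_class(
                row["assigned_pct"], thresholds.good_assigned_pct, thresholds.poor_assigned_pct
            ),
        ]
        if all(c == "good" for c in per_metric):
            labels.append("good")
        elif all(c == "poor" for c in per_metric):
            labels.append("poor")
        else:
            labels.append("medium")
    return pd.Series(labels, index=metrics.index, name="rna_quality")


def select_replicate(replicates: pd.DataFrame) -> str:
    """Pick the replicate with the most assigned reads (ties: lexicographic id).

    Expects columns replicate_id, assigned_reads, m_assigned_reads; ranks
    lexicographically on (assigned_reads, m_assigned_reads) descending.
    """
    if replicates.empty:
        raise ValueError("no replicates supplied")
    df = replicates.sort_values(
        ["assigned_reads", "m_assigned_reads", "replicate_id"],
        ascending=[False, False, True],
    )
    return str(df.iloc[0]["replicate_id"])


def normalize_counts(
    counts: pd.DataFrame, lengths: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RPKM and TPM matrices from raw counts and transcript lengths (bp)."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("invalid transcript lengths")
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError(f"zero library size in samples {list(libsize[libsize == 0].index)}")
    length_kb = lengths / 1e3
    rpkm = counts.div(length_kb, axis=0).div(libsize / 1e6, axis=1)
    rate = counts.div(length_kb, axis=0)
    tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
    return rpkm, tpm


def filter_transcripts(
    counts: pd.DataFrame, min_count_exclusive: int = 9, min_frac: float = 0.30
) -> pd.DataFrame:
    """Keep transcripts with raw counts above ``min_count_exclusive`` in at
    least ``ceil(min_frac * n_samples)`` samples."""
    n_needed = math.ceil(min_frac * counts.shape[1])
    keep = (counts > min_count_exclusive).sum(axis=1) >= n_needed
    return counts.loc[keep]


def filter_tumour_content(sample_meta: pd.DataFrame, minimum: float = 60.0) -> list[str]:
    """Sample ids with tumour content >= ``minimum`` percent.

    Expects columns sample_id and tumour_content; samples with a missing
    annotation are excluded with a warning.
    """
    missing = sample_meta[sample_meta["tumour_content"].isna()]
    if len(missing):
        warnings.warn(
            f"{len(missing)} samples without tumour-content annotation excluded"
        )
    kept = sample_meta[sample_meta["tumour_content"] >= minimum]
    return list(kept["sample_id"])
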