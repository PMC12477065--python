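"""Population allele-frequency annotation and gene-level mutation statistics.

Single-amino-acid-variant NRPs are classified against a reference-population
allele-frequency table: variants absent from the reference population are
"novel" (candidate disease-linked), variants seen in more than 1% of the
population are "frequent" (likely unrelated), and variants in the uncertain
(0, 1%] band are removed. Genes carrying more novel mutations than expected
under the population-wide novel:frequent ratio are flagged with a one-sided
exact binomial test (BH-corrected); deleteriousness scores supplied per
genomic mapping are averaged (scaled C-score >= 20 = deleterious).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

AF_CLASSES = ("novel", "frequent", "removed")


@dataclass(frozen=True)
class AfClassifierParams:
    frequent_threshold: float = 0.01

    def __post_init__(self):
        if not 0 < self.frequent_threshold < 1:
            raise ValueError("frequent_threshold must lie in (0, 1)")


def classify_af(af: float | None, params: AfClassifierParams = AfClassifierParams()) -> str:
    """Classify a reference-population allele frequency.

    Absent (``None``/NaN) or zero AF -> "novel"; AF above the threshold ->
    "frequent"; AF in (0, threshold] -> "removed" (uncertain band).
    """
    if af is None or (isinstance(af, float) and math.isnan(af)):
        return "novel"
    if not 0 <= af <= 1:
        raise ValueError(f"allele frequency {af} outside [0, 1]")
    if af > params.frequent_threshold:
        return "frequent"
    if af > 0:
        return "removed"
    return "novel"


def annotate_afs(
    variant_keys: Sequence[str],
    af_table: Mapping[str, float] | pd.DataFrame,
    params: AfClassifierParams = AfClassifierParams(),
) -> pd.DataFrame:
    """Look up variant keys in an AF table and classify each."""
    if isinstance(af_table, pd.DataFrame):
        af_table = dict(zip(af_table["variant_key"], af_table["af"]))
    rows = []
    for key in variant_keys:
        af = af_table.get(key)
        rows.append({"variant_key": key, "af": af, "af_class": classify_af(af, params)})
    return pd.DataFrame(rows)


def reference_ratio(ref_classes: pd.DataFrame, mode: str = "pooled") -> float:
    """Novel:frequent mutation ratio of the reference population.

    ``pooled`` divides the total novel count by the total frequent count over
    all genes; ``per_gene_mean`` averages the per-gene ratios (genes with no
    frequent mutations are skipped). Expects columns gene_id and af_class.
    """
    df = ref_classes[ref_classes["af_class"].isin(["novel", "frequent"])]
    if mode == "pooled":
        n_nov = (df["af_class"] == "novel").sum()
        n_freq = (df["af_class"] == "frequent").sum()
        if n_freq == 0:
            raise ValueError("no frequent variants in reference table")
        return n_nov / n_freq
    if mode == "per_gene_mean":
        ratios = []
        for _, g in df.groupby("gene_id"):
            n_freq = (g["af_class"] == "frequent").sum()
            if n_freq:
                ratios.append((g["af_class"] == "novel").sum() / n_freq)
        if not ratios:
            raise ValueError("no gene with frequent variants in reference table")
        return float(np.mean(ratios))
    raise ValueError(f"unknown mode {mode!r}")


def gene_excess_test(
    tallies: pd.DataFrame,
    r0: float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided exact binomial test for novel-mutation excess per gene.

    Under the null, each observed mutation of a gene is novel with
    probability p0 = r0 / (1 + r0), the reference population's novel fraction.
    ``excess_p`` is P(X >= n_novel) for X ~ Binomial(n_novel + n_frequent, p0);
    a gene is flagged iff its BH-adjusted p is below ``alpha``. Genes with no
    observed mutations are skipped.

    ``tallies`` needs columns gene_id, n_novel, n_frequent.
    """
    if r0 < 0:
        raise ValueError("reference ratio must be non-negative")
    p0 = r0 / (1.0 + r0)
    df = tallies[(tallies["n_novel"] + tallies["n_frequent"]) >= 1].copy()
    if df.empty:
        return df.assign(excess_p=pd.Series(dtype=float), flagged=pd.Series(dtype=bool))
    pvals = [
        stats.binomtest(int(k), int(k + m), p0, alternative="greater").pvalue
        for k, m in zip(df["n_novel"], df["n_frequent"])
    ]
    df["excess_p"] = pvals
    df["excess_adj_p"] = multipletests(pvals, method="fdr_bh")[1]
    df["flagged"] = df["excess_adj_p"] < alpha
    return df.reset_index(drop=True)


def tally_genes(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-gene counts of novel and frequent mutations (removed ones excluded).

    Expects columns gene_id and af_class; one row per distinct variant.
    """
    df = annotations[annotations["af_class"].isin(["novel", "frequent"])]
    out = (
        df.groupby("gene_id")["af_class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["novel", "frequent"], fill_value=0)
        .rename(columns={"novel": "n_novel", "frequent": "n_frequent"})
        .reset_index()
    )
    out.columns.name = None
    return out


def aggregate_cadd(scores: Sequence[float], threshold: float = 20.0) -> tuple[float | None, bool]:
    """Mean scaled deleteriousness score over genomic mappings, and the flag.

    A variant peptide mappable to several genomic locations gets the mean of
    the per-location scaled C-scores; deleterious iff the mean is >= 20.
    An empty score list yields ``(None, False)`` (annotation absent).
    """
    scores = [s for s in scores if s is not None and not math.isnan(s)]
    if not scores:
        return None, False
    mean = float(np.mean(scores))
    return mean, mean >= threshold


BREADTH_BINS = ((1, 2), (3, 5), (6, 10), (11, None))


def _breadth_bin(n: int) -> str:
    for lo, hi in BREADTH_BINS:
        if hi is None and n >= lo:
            return f"{lo}+ patients"
        if lo <= n <= hi:
            return f"{lo}-{hi} patients"
    return "0 patients"


def summarize_catalog(catalog: pd.DataFrame) -> dict:
    """Cohort-level summary of the annotated NRP catalogue.

    Expects columns variant_class, n_patients and (optionally) af_class and
    deleterious. Returns per-class counts, patient-breadth bins and the mean
    patient breadth.
    """
    summary = {
        "n_nrps": int(len(catalog)),
        "counts_by_class": catalog["variant_class"].value_counts().to_dict(),
        "counts_by_breadth": catalog["n_patients"].map(_breadth_bin).value_counts().to_dict(),
        "mean_patient_breadth": float(catalog["n_patients"].mean()) if len(catalog) else float("nan"),
    }
    if "af_class" in catalog:
        summary["counts_by_af_class"] = catalog["af_class"].value_counts().to_dict()
    if "deleterious" in catalog:
        summary["n_deleterious"] = int(catalog["deleterious"].sum())
    return summary
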