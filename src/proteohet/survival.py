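"""Survival analysis: Kaplan-Meier, log-rank, Cox models, gene ranking for
survival GSEA, single-sample signature scores and majority-cluster patient
classification.

Estimation is delegated to lifelines; this module adds the cohort-specific
conventions: patient-level collapsing of multi-metastasis abundance before
per-protein Cox ranking (the pseudo-replication control), the signed-z
ranking convention where positive scores mean upregulation in patients with
shorter overall survival, and the >50% majority rule for calling a patient's
dominant cluster pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats


@dataclass
class KmResult:
    survival: pd.DataFrame  # columns: time, s (product-limit estimate)
    median: float  # smallest time with S(t) <= 0.5; inf if never reached
    median_ci: tuple[float, float]
    greenwood_var: pd.Series  # Var[S(t)] at each event time


def greenwood_variance(times: np.ndarray, events: np.ndarray) -> pd.Series:
    """Greenwood variance of the Kaplan-Meier estimate at each event time."""
    order = np.argsort(times, kind="mergesort")
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    uniq = np.unique(times[events == 1])
    s = 1.0
    acc = 0.0
    out = {}
    for t in uniq:
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1 - d / n_at_risk
        if n_at_risk - d > 0:
            acc += d / (n_at_risk * (n_at_risk - d))
            out[t] = s * s * acc
        else:
            out[t] = 0.0
    return pd.Series(out, name="greenwood_var")


def km_estimate(records: pd.DataFrame) -> KmResult:
    """Product-limit survival estimate with Greenwood variance.

    ``records`` needs columns ``time`` (months, > 0) and ``event``
    (1 = death, 0 = censored).
    """
    if records.empty:
        raise ValueError("no survival records")
    if (records["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    surv = kmf.survival_function_.reset_index()
    surv.columns = ["time", "s"]
    median = float(kmf.median_survival_time_)
    try:
        from lifelines.utils import median_survival_times

        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    except Exception:  # pragma: no cover
        lo, hi = float("nan"), float("nan")
    gv = greenwood_variance(records["time"].to_numpy(), records["event"].to_numpy())
    return KmResult(surv, median, (lo, hi), gv)


def logrank(records: pd.DataFrame, group_col: str = "group") -> tuple[float, float]:
    """Log-rank test across groups: returns (chi-square statistic, p)."""
    groups = records[group_col].unique()
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(records["time"], records[group_col], records["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    summary: pd.DataFrame  # per covariate: coef, hr, ci_lower, ci_upper, p, z
    converged: bool
    n: int
    n_events: int

    def z(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "z"])

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def cox_fit(
    records: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
) -> CoxFit:
    """Cox proportional-hazards fit over the given covariates.

    Non-convergence or separation is flagged (``converged=False``) rather
    than silently returned.
    """
    df = records[[duration_col, event_col, *covariates]].dropna()
    if df[event_col].sum() < 1:
        raise ValueError("no events in the data")
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"constant covariate {c!r}")
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col=duration_col, event_col=event_col)
        except Exception:
            converged = False
    if not converged:
        empty = pd.DataFrame(
            np.nan, index=list(covariates), columns=["coef", "hr", "ci_lower", "ci_upper", "p", "z"]
        )
        return CoxFit(empty, False, len(df), int(df[event_col].sum()))
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
            "z": s["z"],
        }
    )
    return CoxFit(out, True, len(df), int(df[event_col].sum()))


def rank_genes_by_survival(
    abundance: pd.DataFrame,
    clinical: pd.DataFrame,
    patient_map: Mapping[str, str],
    max_missing_patient_frac: float = 0.5,
) -> pd.DataFrame:
    """Rank proteins by their association with overall survival.

    Metastasis samples are collapsed to one value per patient (the mean) to
    remove pseudo-replication, then each protein gets a univariate Cox fit on
    the patient-level values. The ranking score is the signed z-statistic,
    descending: positive means higher abundance in patients with shorter
    survival (the NES > 0 convention downstream).

    ``clinical`` is patient-level with columns patient_id, time, event.
    """
    patients = clinical.set_index("patient_id")
    cols_by_patient: dict[str, list[str]] = {}
    for s in abundance.columns:
        p = patient_map.get(s)
        if p in patients.index:
            cols_by_patient.setdefault(p, []).append(s)
    plist = sorted(cols_by_patient)
    collapsed = pd.DataFrame(
        {p: abundance[cols_by_patient[p]].mean(axis=1, skipna=True) for p in plist}
    )
    rows = []
    for prot in collapsed.index:
        vals = collapsed.loc[prot]
        if vals.isna().mean() > max_missing_patient_frac:
            warnings.warn(f"protein {prot} missing in >50% of patients; excluded")
            continue
        df = pd.DataFrame(
            {
                "time": patients.loc[plist, "time"].to_numpy(),
                "event": patients.loc[plist, "event"].to_numpy(),
                "x": vals.loc[plist].to_numpy(),
            }
        ).dropna()
        if df["x"].nunique() < 2 or df["event"].sum() < 1:
            continue
        fit = cox_fit(df, ["x"])
        if fit.converged and np.isfinite(fit.z("x")):
            rows.append({"protein": prot, "z": fit.z("x"), "hr": fit.hazard_ratio("x")})
    out = pd.DataFrame(rows, columns=["protein", "z", "hr"])
    out = out.sort_values("z", ascending=False).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def signature_score(
    z_matrix: pd.DataFrame,
    marker_sets: Mapping[str, Sequence[str]],
    min_genes: int = 3,
) -> pd.DataFrame:
    """Single-sample signature scores: mean z over the signature's genes.

    ``z_matrix`` is genes x samples, z-scored per gene. Signatures with fewer
    than ``min_genes`` genes present in the matrix get NaN scores.
    """
    out = {}
    for name, genes in marker_sets.items():
        present = [g for g in set(genes) if g in z_matrix.index]
        if len(present) < min_genes:
            out[name] = pd.Series(np.nan, index=z_matrix.columns)
        else:
            out[name] = z_matrix.loc[present].mean(axis=0)
    return pd.DataFrame(out)


def score_cluster_association(scores: pd.DataFrame, assignments: pd.Series) -> pd.Series:
    """Kruskal-Wallis p-value per signature across clusters (convenience)."""
    common = scores.index.intersection(assignments.index)
    labels = assignments.loc[common]
    out = {}
    for sig in scores.columns:
        groups = [
            scores.loc[common[labels == c], sig].dropna() for c in sorted(labels.unique())
        ]
        groups = [g for g in groups if len(g)]
        out[sig] = (
            stats.kruskal(*groups)[1] if len(groups) >= 2 else float("nan")
        )
    return pd.Series(out, name="kruskal_p")


def majority_cluster_class(
    assignments: pd.Series,
    patient_map: Mapping[str, str],
    target_clusters: Sequence = (0, 2),
) -> pd.Series:
    """Classify patients by their dominant cluster pair.

    A patient is "dominant" iff strictly more than 50% of their clustered
    metastases fall in ``target_clusters``; exactly 50% counts as "other".
    Patients with zero clustered metastases are excluded.
    """
    targets = set(target_clusters)
    counts: dict[str, list[int]] = {}
    for sample, cluster in assignments.items():
        p = patient_map.get(sample)
        if p is None:
            continue
        tot_hit = counts.setdefault(p, [0, 0])
        tot_hit[0] += 1
        if cluster in targets:
            tot_hit[1] += 1
    out = {
        p: ("dominant" if hit / tot > 0.5 else "other")
        for p, (tot, hit) in counts.items()
        if tot > 0
    }
    return pd.Series(out, name="majority_class").sort_index()
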