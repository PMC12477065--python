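"""Heterogeneity statistics: consensus clustering, differential abundance,
Fisher NRP enrichment, pre-ranked GSEA, protein-RNA correlation, similarity.

Consensus clustering resamples subsets of samples, clusters each subset with
partition-around-medoids (PAM) on 1 - Pearson correlation distance, and
aggregates co-clustering frequencies; the number of clusters is chosen from
the delta-area curve of the consensus CDF. Differential abundance uses
Welch's t-test on log2 intensities with BH correction; cluster-specific
upregulation requires a protein to beat every other cluster. NRP enrichment
uses a one-sided Fisher exact test, and pathway-level statements come from a
classic weighted running-sum pre-ranked GSEA with gene-label permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------- clustering


def pam(distance: np.ndarray, k: int, seed: int | None = None, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Partition around medoids (BUILD + SWAP) on a distance matrix.

    Returns ``(assignments, medoid_indices)``. The algorithm is
    deterministic: BUILD greedily picks the medoid minimising total cost,
    SWAP takes the best improving (medoid, non-medoid) exchange until no swap
    improves the total within-cluster distance. Small instances (where the
    number of candidate medoid sets is tiny) are solved exactly by
    enumeration, so local optima cannot occur there. ``seed`` is accepted
    for interface symmetry; ties break on the lowest index.
    """
    import itertools as _it
    from math import comb

    D = np.asarray(distance, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < -1e-12):
        raise ValueError("distance matrix must be non-negative")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")

    if comb(n, k) * n <= 50_000:  # exact enumeration for small instances
        best_cost, best_meds = np.inf, None
        for meds in _it.combinations(range(n), k):
            c = float(D[:, meds].min(axis=1).sum())
            if c < best_cost - 1e-12:
                best_cost, best_meds = c, meds
        medoids = sorted(best_meds)
        assignments = np.argmin(D[:, medoids], axis=1)
        return assignments, np.array(medoids, dtype=int)

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    def cost(meds: Sequence[int]) -> float:
        return float(D[:, list(meds)].min(axis=1).sum())

    best_cost = cost(medoids)
    for _ in range(max_iter):
        improved = False
        best_swap = None
        non_medoids = [i for i in range(n) if i not in medoids]
        for mi, m in enumerate(medoids):
            trial = list(medoids)
            for h in non_medoids:
                trial[mi] = h
                c = cost(trial)
                if c < best_cost - 1e-12:
                    best_cost = c
                    best_swap = (mi, h)
            # restore handled by rebuilding trial each outer loop
        if best_swap is not None:
            medoids[best_swap[0]] = best_swap[1]
            improved = True
        if not improved:
            break
    medoids = sorted(medoids)
    assignments = np.argmin(D[:, medoids], axis=1)
    return assignments, np.array(medoids, dtype=int)


def pearson_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between sample columns."""
    sds = matrix.std(axis=0, ddof=0)
    constant = list(sds[sds == 0].index)
    if constant:
        raise ValueError(f"constant-valued samples (undefined correlation): {constant}")
    return 1.0 - matrix.corr(method="pearson")


@dataclass(frozen=True)
class ConsensusParams:
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_resamples: int = 1000
    sample_frac: float = 0.8
    distance: str = "pearson"
    seed: int = 0
    quantified_frac_min: float = 0.90
    elbow_threshold: float = 0.1

    def __post_init__(self):
        if min(self.k_range) < 2:
            raise ValueError("k must be >= 2")
        if not 0 < self.sample_frac <= 1:
            raise ValueError("sample_frac must lie in (0, 1]")


@dataclass
class ConsensusResult:
    consensus: dict[int, pd.DataFrame]
    assignments: dict[int, pd.Series]
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int
    medoids: dict[int, list[str]] = field(default_factory=dict)


def _consensus_cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    iu = np.triu_indices(consensus.shape[0], k=1)
    x = np.sort(consensus[iu])
    m = len(x)
    if m == 0:
        return 0.0
    # A = sum_i (x_i - x_{i-1}) * CDF(x_{i-1}) over the sorted support
    xs = np.concatenate([x, [1.0]])
    cdf = np.arange(1, m + 1) / m
    return float(np.sum(np.diff(xs) * cdf))


def consensus_cluster(matrix: pd.DataFrame, params: ConsensusParams = ConsensusParams()) -> ConsensusResult:
    """Consensus clustering of sample columns with PAM on Pearson distance.

    For each k, ``n_resamples`` random subsets of ``sample_frac`` of the
    samples are clustered; consensus[i, j] is the fraction of co-samplings in
    which i and j co-clustered. Final assignments at each k come from PAM on
    1 - consensus. ``chosen_k`` is the largest k whose relative increase in
    consensus-CDF area is at least ``elbow_threshold``.

    The computation runs in canonical (sorted) sample order and results are
    reindexed to the input order, so permuting input columns permutes the
    output identically.
    """
    frac = matrix.notna().mean(axis=1)
    use = matrix.loc[frac >= params.quantified_frac_min]
    if use.isna().any().any():
        raise ValueError("consensus clustering requires a complete (imputed) matrix")
    order = sorted(use.columns)
    use = use[order]
    n = len(order)
    D_full = pearson_distance(use).to_numpy()
    D_full = np.maximum(D_full, 0.0)

    rng = np.random.default_rng(params.seed)
    m = max(2, int(np.floor(params.sample_frac * n)))
    ks = sorted(params.k_range)

    consensus, assignments, areas, medoid_names = {}, {}, {}, {}
    for k in ks:
        co = np.zeros((n, n))
        tog = np.zeros((n, n))
        rng_k = np.random.default_rng(rng.integers(2**31))
        for _ in range(params.n_resamples):
            idx = np.sort(rng_k.choice(n, size=m, replace=False))
            sub = D_full[np.ix_(idx, idx)]
            labels, _ = pam(sub, k)
            same = labels[:, None] == labels[None, :]
            co[np.ix_(idx, idx)] += same
            tog[np.ix_(idx, idx)] += 1
        with np.errstate(invalid="ignore"):
            cons = np.where(tog > 0, co / np.maximum(tog, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2
        labels, med = pam(np.maximum(1.0 - cons, 0.0), k)
        consensus[k] = pd.DataFrame(cons, index=order, columns=order)
        assignments[k] = pd.Series(labels, index=order, name=f"k{k}")
        medoid_names[k] = [order[i] for i in med]
        areas[k] = _consensus_cdf_area(cons)

    delta = {}
    prev = None
    for k in ks:
        if prev is None:
            delta[k] = areas[k]
        else:
            delta[k] = max(0.0, (areas[k] - areas[prev]) / areas[prev]) if areas[prev] > 0 else 0.0
        prev = k
    eligible = [k for k in ks if delta[k] >= params.elbow_threshold]
    chosen_k = max(eligible) if eligible else ks[0]

    in_order = [c for c in matrix.columns if c in set(order)]
    consensus = {k: df.loc[in_order, in_order] for k, df in consensus.items()}
    assignments = {k: s.loc[in_order] for k, s in assignments.items()}
    return ConsensusResult(consensus, assignments, areas, delta, chosen_k, medoid_names)


# ------------------------------------------------------- differential tests


def differential_abundance(
    matrix: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.DataFrame:
    """Welch two-sample t-test per protein; effect = mean(A) - mean(B), BH adj.

    Zero-variance-in-both-groups proteins get p = 1 when means are equal.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    A = matrix[list(group_a)].to_numpy(dtype=float)
    B = matrix[list(group_b)].to_numpy(dtype=float)
    effect = np.nanmean(A, axis=1) - np.nanmean(B, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    p[degenerate & (np.abs(effect) < 1e-12)] = 1.0
    p[degenerate & (np.abs(effect) >= 1e-12)] = 0.0
    adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"effect": effect, "p": p, "adj_p": adj}, index=matrix.index
    )


def cluster_specific_upregulation(
    matrix: pd.DataFrame,
    assignments: pd.Series,
    alpha: float = 0.05,
) -> dict:
    """Proteins specifically upregulated in each cluster.

    A protein is specific to cluster c iff, against every other cluster c',
    its effect is positive and the BH-adjusted p (within that pairwise
    contrast) is below ``alpha``. Clusters of size < 2 are excluded from
    contrasts with a warning.
    """
    clusters = sorted(assignments.unique())
    sizes = assignments.value_counts()
    usable = [c for c in clusters if sizes[c] >= 2]
    skipped = [c for c in clusters if sizes[c] < 2]
    if skipped:
        warnings.warn(f"clusters of size <2 excluded from contrasts: {skipped}")
    pair_results: dict[tuple, pd.DataFrame] = {}
    for c in usable:
        for c2 in usable:
            if c2 == c:
                continue
            ga = list(assignments[assignments == c].index)
            gb = list(assignments[assignments == c2].index)
            pair_results[(c, c2)] = differential_abundance(matrix, ga, gb)
    out = {}
    for c in usable:
        ok = np.ones(len(matrix.index), dtype=bool)
        for c2 in usable:
            if c2 == c:
                continue
            res = pair_results[(c, c2)]
            ok &= (res["effect"] > 0).to_numpy() & (res["adj_p"] < alpha).to_numpy()
        out[c] = list(matrix.index[ok])
    return out


def fisher_enrichment(
    presence: Sequence[int], in_group: Sequence[bool], alternative: str = "greater"
) -> float:
    """One-sided Fisher exact p for over-representation of presence in a group.

    The 2x2 table is presence x group membership over the analysis samples.
    An all-zero presence row returns p = 1.
    """
    presence = np.asarray(presence, dtype=bool)
    in_group = np.asarray(in_group, dtype=bool)
    if presence.shape != in_group.shape:
        raise ValueError("presence and group vectors differ in length")
    if not presence.any():
        return 1.0
    a = int(np.sum(presence & in_group))
    b = int(np.sum(presence & ~in_group))
    c = int(np.sum(~presence & in_group))
    d = int(np.sum(~presence & ~in_group))
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


# ------------------------------------------------------------------- GSEA


def gsea_enrichment_score(
    ranked_scores: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0
) -> float:
    """Classic weighted Kolmogorov-Smirnov-like running-sum enrichment score.

    ``ranked_scores`` must be sorted descending; hits increment the running
    sum proportionally to |score|^weight, misses decrement uniformly; the ES
    is the maximum deviation from zero (sign retained).
    """
    hit_mask = np.asarray(hit_mask, dtype=bool)
    n = len(ranked_scores)
    nh = int(hit_mask.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must be a proper non-empty subset of the ranking")
    w = np.abs(ranked_scores) ** weight
    hit_sum = w[hit_mask].sum()
    steps = np.where(hit_mask, w / hit_sum if hit_sum > 0 else 0.0, -1.0 / (n - nh))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


@dataclass
class GseaResult:
    table: pd.DataFrame  # per gene set: size, es, nes, p, adj_p


def preranked_gsea(
    scores: pd.Series,
    gene_sets: Mapping[str, Sequence[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 10,
) -> GseaResult:
    """Pre-ranked GSEA with gene-label permutation p-values.

    Genes are ranked by ``scores`` descending. Each set is intersected with
    the ranked universe; sets with fewer than ``min_size`` members are
    skipped with a warning. NES = ES / mean(|permuted ES| of the same sign);
    p is the same-sign permutation tail with add-one smoothing; BH across
    sets.
    """
    if scores.isna().any():
        raise ValueError("ranking metric contains missing values")
    ranked = scores.sort_values(ascending=False, kind="mergesort")
    ranked = ranked.loc[sorted(ranked.index, key=lambda g: (-scores[g], g))]
    genes = np.array(ranked.index)
    vals = ranked.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    for name in sorted(gene_sets):
        members = [g for g in set(gene_sets[name]) if g in gene_pos]
        if len(members) < min_size:
            warnings.warn(f"gene set {name!r} skipped (<{min_size} members in universe)")
            continue
        if len(members) >= len(genes):
            warnings.warn(f"gene set {name!r} skipped (covers the whole universe)")
            continue
        mask = np.zeros(len(genes), dtype=bool)
        mask[[gene_pos[g] for g in members]] = True
        es = gsea_enrichment_score(vals, mask, weight)

        m = len(members)
        perm_es = np.empty(n_perm)
        for i in range(n_perm):
            pmask = np.zeros(len(genes), dtype=bool)
            pmask[rng.choice(len(genes), size=m, replace=False)] = True
            perm_es[i] = gsea_enrichment_score(vals, pmask, weight)
        same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        if len(same_sign):
            nes = es / np.mean(np.abs(same_sign))
            p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + len(same_sign))
        else:
            nes, p = np.nan, 1.0
        rows.append({"gene_set": name, "size": m, "es": es, "nes": nes, "p": p})

    table = pd.DataFrame(rows, columns=["gene_set", "size", "es", "nes", "p"])
    if len(table):
        table["adj_p"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["adj_p"] = pd.Series(dtype=float)
    return GseaResult(table.set_index("gene_set"))


# ------------------------------------------------- correlation & similarity


def genewise_spearman(
    protein: pd.DataFrame,
    rna: pd.DataFrame,
    min_pairs: int = 3,
    rho_threshold: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Spearman correlation between protein and RNA matrices.

    Rows are genes, columns samples; the matrices are aligned on shared genes
    and samples. Genes with fewer than ``min_pairs`` pairwise-complete
    observations are skipped. The strong-positive flag requires
    rho > ``rho_threshold`` and BH-adjusted p < ``alpha``.
    """
    genes = protein.index.intersection(rna.index)
    samples = protein.columns.intersection(rna.columns)
    rows = []
    for g in genes:
        x = protein.loc[g, samples].to_numpy(dtype=float)
        y = rna.loc[g, samples].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < min_pairs:
            continue
        rho, p = stats.spearmanr(x[ok], y[ok])
        rows.append({"gene_id": g, "rho": rho, "p": p, "n": int(ok.sum())})
    out = pd.DataFrame(rows, columns=["gene_id", "rho", "p", "n"])
    if len(out):
        out["adj_p"] = multipletests(out["p"].fillna(1.0), method="fdr_bh")[1]
        out["strong_positive"] = (out["rho"] > rho_threshold) & (out["adj_p"] < alpha)
    return out


def similarity_matrices(
    abundance: pd.DataFrame, presence: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise sample similarity: Pearson (abundance) and Jaccard (presence).

    Pearson uses pairwise-complete observations. Jaccard(i, j) is the ratio
    of shared to united NRP presences (1 when both samples are empty).
    """
    pearson = abundance.corr(method="pearson")
    P = presence.to_numpy(dtype=bool)
    n = P.shape[1]
    jac = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = np.sum(P[:, i] & P[:, j])
            union = np.sum(P[:, i] | P[:, j])
            jac[i, j] = jac[j, i] = inter / union if union else 1.0
    jaccard = pd.DataFrame(jac, index=presence.columns, columns=presence.columns)
    return pearson, jaccard
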