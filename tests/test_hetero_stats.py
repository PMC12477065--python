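"""Heterogeneity statistics: PAM vs exhaustive medoid search, consensus
clustering recovery, Welch differential abundance, Fisher enrichment vs the
hypergeometric oracle, GSEA vs an independent running-sum oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from proteohet.hetero_stats import (
    ConsensusParams,
    cluster_specific_upregulation,
    consensus_cluster,
    differential_abundance,
    fisher_enrichment,
    genewise_spearman,
    gsea_enrichment_score,
    pam,
    pearson_distance,
    preranked_gsea,
    similarity_matrices,
)


def exhaustive_pam_cost(D, k):
    """Oracle: minimum total distance over all medoid subsets."""
    n = D.shape[0]
    return min(
        D[:, list(m)].min(axis=1).sum() for m in itertools.combinations(range(n), k)
    )


class TestPam:
    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            pts = rng.normal(size=(9, 2))
            D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            for k in (2, 3):
                labels, medoids = pam(D, k)
                cost = D[:, medoids].min(axis=1).sum()
                assert cost == pytest.approx(exhaustive_pam_cost(D, k), rel=1e-9)

    def test_two_blobs(self):
        pts = np.concatenate([np.zeros((5, 2)), np.full((5, 2), 10.0)])
        pts += np.random.default_rng(1).normal(0, 0.1, pts.shape)
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels, _ = pam(D, 2)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[9]

    def test_k_equals_n(self):
        D = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0)))
        labels, medoids = pam(D, 4)
        assert sorted(medoids) == [0, 1, 2, 3]
        assert D[:, medoids].min(axis=1).sum() == 0

    def test_duplicates_cluster_together(self):
        D = np.array(
            [[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 0], [5, 5, 0, 0]], dtype=float
        )
        labels, _ = pam(D, 2)
        assert labels[0] == labels[1] and labels[2] == labels[3]

    def test_k_too_large_error(self):
        with pytest.raises(ValueError):
            pam(np.zeros((3, 3)), 4)


def planted_matrix(seed, n_per_cluster=6, n_clusters=4, n_genes=80, effect=5.0, sd=1.0):
    rng = np.random.default_rng(seed)
    blocks = np.array_split(np.arange(n_genes), n_clusters)
    cols, labels = {}, {}
    for c in range(n_clusters):
        for i in range(n_per_cluster):
            name = f"c{c}s{i}"
            x = rng.normal(20, sd, n_genes)
            x[blocks[c]] += effect * sd
            cols[name] = x
            labels[name] = c
    return pd.DataFrame(cols), pd.Series(labels)


class TestConsensus:
    def test_recovers_planted_clusters(self):
        mat, truth = planted_matrix(0)
        params = ConsensusParams(k_range=(2, 3, 4, 5), n_resamples=60, seed=1)
        res = consensus_cluster(mat, params)
        assert res.chosen_k == 4
        ari = adjusted_rand_score(truth[res.assignments[4].index], res.assignments[4])
        assert ari == 1.0

    def test_consensus_entries_for_coclustered_pairs(self):
        mat, truth = planted_matrix(2)
        params = ConsensusParams(k_range=(4,), n_resamples=40, seed=2)
        res = consensus_cluster(mat, params)
        cons = res.consensus[4]
        same = [p for p in itertools.combinations(mat.columns, 2) if truth[p[0]] == truth[p[1]]]
        vals = [cons.loc[a, b] for a, b in same]
        assert min(vals) == pytest.approx(1.0)

    def test_column_permutation_invariance(self):
        mat, _ = planted_matrix(3, n_per_cluster=4, n_genes=40)
        params = ConsensusParams(k_range=(2, 3, 4), n_resamples=30, seed=3)
        res_a = consensus_cluster(mat, params)
        shuffled = mat[list(reversed(mat.columns))]
        res_b = consensus_cluster(shuffled, params)
        a = res_a.assignments[4]
        b = res_b.assignments[4].loc[a.index]
        assert adjusted_rand_score(a, b) == 1.0
        assert res_a.chosen_k == res_b.chosen_k

    def test_constant_sample_error(self):
        mat = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0], "c": [2.0, 1.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            pearson_distance(mat)

    def test_chance_structure_low_ari(self):
        """Without planted effect the recovered labels are near-chance."""
        aris = []
        for seed in range(8):
            mat, truth = planted_matrix(seed + 10, n_per_cluster=5, n_genes=40, effect=0.0)
            params = ConsensusParams(k_range=(4,), n_resamples=25, seed=seed)
            res = consensus_cluster(mat, params)
            aris.append(adjusted_rand_score(truth[res.assignments[4].index], res.assignments[4]))
        assert np.mean(aris) < 0.2


class TestDifferentialAbundance:
    def test_identical_groups(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a1", "a2", "a3"])
        dup = mat.copy()
        dup.columns = ["b1", "b2", "b3"]
        both = pd.concat([mat, dup], axis=1)
        res = differential_abundance(both, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert np.allclose(res["effect"], 0)
        assert np.allclose(res["p"], 1.0)

    def test_planted_shift_power(self):
        hits = 0
        n_sim = 40
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            mat = pd.DataFrame(rng.normal(0, 1, size=(50, 20)))
            mat.columns = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
            mat.iloc[0, :10] += 5.0  # 5 within-group sd shift
            res = differential_abundance(mat, [f"a{i}" for i in range(10)], [f"b{i}" for i in range(10)])
            hits += res["adj_p"].iloc[0] < 0.05
        assert hits / n_sim >= 0.95

    def test_bh_monotone(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.normal(size=(40, 8)))
        res = differential_abundance(mat, list(mat.columns[:4]), list(mat.columns[4:]))
        assert (res["adj_p"] >= res["p"] - 1e-12).all()
        srt = res.sort_values("p")
        assert srt["adj_p"].is_monotonic_increasing

    def test_cluster_specific_upregulation(self):
        rng = np.random.default_rng(6)
        cols = [f"s{i}" for i in range(20)]
        assign = pd.Series([i // 5 for i in range(20)], index=cols)
        mat = pd.DataFrame(rng.normal(0, 0.3, size=(30, 20)), columns=cols)
        mat.iloc[0, 0:5] += 5.0  # specific to cluster 0
        mat.iloc[1, 0:10] += 5.0  # elevated in clusters 0 and 1 equally
        sets = cluster_specific_upregulation(mat, assign)
        assert 0 in sets[0] and all(0 not in sets[c] for c in (1, 2, 3))
        assert all(1 not in sets[c] for c in sets)


def hypergeom_tail_oracle(a, b, c, d):
    """P(X >= a) for X ~ Hypergeom(N=a+b+c+d, K=a+b, n=a+c)."""
    N, K, n = a + b + c + d, a + b, a + c
    total = 0.0
    for x in range(a, min(K, n) + 1):
        if n - x <= N - K:
            total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


class TestFisher:
    def test_3_0_0_7_table(self):
        presence = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        group = [True] * 3 + [False] * 7
        assert fisher_enrichment(presence, group) == pytest.approx(1 / 120, rel=1e-9)

    def test_all_zero_presence(self):
        assert fisher_enrichment([0, 0, 0, 0], [True, True, False, False]) == 1.0

    def test_exhaustive_small_tables(self):
        for n in range(2, 13):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        if a + b == 0:
                            continue
                        presence = [1] * a + [1] * b + [0] * c + [0] * d
                        group = [True] * a + [False] * b + [True] * c + [False] * d
                        got = fisher_enrichment(presence, group)
                        assert got == pytest.approx(
                            hypergeom_tail_oracle(a, b, c, d), abs=1e-12
                        )


def gsea_oracle(scores, gene_set, weight=1.0):
    """Independent running-sum implementation (explicit loop)."""
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    in_set = [g in gene_set for g in order]
    nh = sum(in_set)
    nm = len(order) - nh
    denom = sum(abs(scores[g]) ** weight for g, h in zip(order, in_set) if h)
    running, best = 0.0, 0.0
    for g, h in zip(order, in_set):
        if h:
            running += abs(scores[g]) ** weight / denom if denom else 0.0
        else:
            running -= 1.0 / nm
        if abs(running) > abs(best):
            best = running
    return best


class TestGsea:
    def scores(self, seed, n=50):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])

    def test_top_genes_high_es(self):
        s = pd.Series(
            np.concatenate([np.full(5, 10.0), np.linspace(1, -1, 95)]),
            index=[f"g{i}" for i in range(100)],
        )
        es = gsea_enrichment_score(
            s.sort_values(ascending=False).to_numpy(),
            np.array([True] * 5 + [False] * 95),
        )
        assert es > 0.9

    def test_matches_oracle_random_instances(self):
        for seed in range(100):
            s = self.scores(seed, n=int(20 + (seed % 31)))
            rng = np.random.default_rng(seed + 1000)
            size = int(rng.integers(3, 10))
            members = set(rng.choice(s.index, size=size, replace=False))
            ranked = s.loc[sorted(s.index, key=lambda g: (-s[g], g))]
            mask = np.array([g in members for g in ranked.index])
            got = gsea_enrichment_score(ranked.to_numpy(), mask)
            assert got == pytest.approx(gsea_oracle(s, members), abs=1e-12)

    def test_mirrored_ranking_negates_es(self):
        s = self.scores(7)
        members = set(s.index[:8])
        ranked = s.loc[sorted(s.index, key=lambda g: (-s[g], g))]
        mask = np.array([g in members for g in ranked.index])
        es = gsea_enrichment_score(ranked.to_numpy(), mask)
        neg = -s
        ranked_n = neg.loc[sorted(neg.index, key=lambda g: (-neg[g], g))]
        mask_n = np.array([g in members for g in ranked_n.index])
        es_n = gsea_enrichment_score(ranked_n.to_numpy(), mask_n)
        assert es_n == pytest.approx(-es, abs=1e-12)

    def test_small_sets_skipped(self):
        s = self.scores(8)
        with pytest.warns(UserWarning, match="skipped"):
            res = preranked_gsea(s, {"tiny": list(s.index[:3])}, n_perm=10, seed=0)
        assert res.table.empty

    def test_permutation_p_stable_across_seeds(self):
        s = self.scores(9, n=60)
        sets = {"set1": list(s.index[:15])}
        p1 = preranked_gsea(s, sets, n_perm=2000, seed=1).table["p"].iloc[0]
        p2 = preranked_gsea(s, sets, n_perm=2000, seed=2).table["p"].iloc[0]
        se = math.sqrt(p1 * (1 - p1) / 2000)
        assert abs(p1 - p2) <= 3 * max(se, 1 / 2000) + 1e-12


class TestSpearman:
    def test_monotone_vectors(self):
        prot = pd.DataFrame([[1.0, 2, 3, 4, 5], [5, 4, 3, 2, 1]], index=["up", "down"])
        rna = pd.DataFrame([[2.0, 3, 5, 8, 9], [2.0, 3, 5, 8, 9]], index=["up", "down"])
        out = genewise_spearman(prot, rna).set_index("gene_id")
        assert out.loc["up", "rho"] == pytest.approx(1.0)
        assert out.loc["down", "rho"] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            x = rng.integers(0, 4, size=12).astype(float)
            y = rng.integers(0, 4, size=12).astype(float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            prot = pd.DataFrame([x], index=["g"])
            rna = pd.DataFrame([y], index=["g"])
            got = genewise_spearman(prot, rna)["rho"].iloc[0]
            oracle = sps.pearsonr(sps.rankdata(x), sps.rankdata(y))[0]
            assert got == pytest.approx(oracle, abs=1e-12)

    def test_few_pairs_skipped(self):
        prot = pd.DataFrame([[1.0, np.nan, np.nan, 4]], index=["g"])
        rna = pd.DataFrame([[1.0, 2, 3, 4]], index=["g"])
        assert genewise_spearman(prot, rna).empty


class TestSimilarity:
    def test_jaccard_examples(self):
        presence = pd.DataFrame(
            {"s1": [1, 1, 0], "s2": [0, 1, 1], "s3": [0, 0, 0]}, index=["a", "b", "c"]
        )
        abundance = pd.DataFrame(
            {"s1": [1.0, 2, 3], "s2": [1.0, 2, 3], "s3": [3.0, 2, 1]}
        )
        pearson, jaccard = similarity_matrices(abundance, presence)
        assert jaccard.loc["s1", "s2"] == pytest.approx(1 / 3)
        assert jaccard.loc["s1", "s1"] == 1.0
        assert jaccard.loc["s3", "s3"] == 1.0  # both empty -> 1
        assert pearson.loc["s1", "s2"] == pytest.approx(1.0)

    def test_disjoint_presence(self):
        presence = pd.DataFrame({"s1": [1, 0], "s2": [0, 1]})
        abundance = pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 1.0]})
        _, jaccard = similarity_matrices(abundance, presence)
        assert jaccard.loc["s1", "s2"] == 0.0
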