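"""Survival analysis: Kaplan-Meier/Greenwood hand checks, log-rank, Cox
recovery against a numeric partial-likelihood oracle, gene ranking and the
majority-cluster rule."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from proteohet.survival import (
    cox_fit,
    greenwood_variance,
    km_estimate,
    logrank,
    majority_cluster_class,
    rank_genes_by_survival,
    signature_score,
)


def records(times, events):
    return pd.DataFrame({"time": times, "event": events})


class TestKm:
    def test_hand_product_limit(self):
        res = km_estimate(records([1, 2, 3], [1, 1, 1]))
        s = res.survival.set_index("time")["s"]
        assert s.loc[1] == pytest.approx(2 / 3)
        assert s.loc[2] == pytest.approx(1 / 3)
        assert s.loc[3] == pytest.approx(0.0)
        assert res.median == pytest.approx(2.0)

    def test_all_censored(self):
        res = km_estimate(records([1, 2, 3], [0, 0, 0]))
        assert (res.survival["s"] == 1.0).all()
        assert np.isinf(res.median)

    def test_greenwood_hand_computed_5_records(self):
        # times 1,2,3 events; 4,5 censored after
        gv = greenwood_variance(np.array([1, 2, 3, 4, 5]), np.array([1, 1, 1, 0, 0]))
        # t=1: S=4/5, var = S^2 * [1/(5*4)] = 0.64*0.05 = 0.032
        assert gv.loc[1] == pytest.approx((4 / 5) ** 2 * (1 / 20))
        # t=2: S=4/5*3/4=3/5, acc=1/20+1/12
        assert gv.loc[2] == pytest.approx((3 / 5) ** 2 * (1 / 20 + 1 / 12))
        # t=3: S=3/5*2/3=2/5, acc=1/20+1/12+1/6
        assert gv.loc[3] == pytest.approx((2 / 5) ** 2 * (1 / 20 + 1 / 12 + 1 / 6))

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, size=50).round(3)
        res = km_estimate(records(t, np.ones(50, dtype=int)))
        s = res.survival.set_index("time")["s"]
        for time in sorted(t)[:10]:
            assert s.loc[time] == pytest.approx(np.mean(t > time))


class TestLogrank:
    def test_identical_groups(self):
        df = pd.DataFrame(
            {
                "time": [1, 2, 3, 1, 2, 3],
                "event": [1, 1, 1, 1, 1, 1],
                "group": ["a", "a", "a", "b", "b", "b"],
            }
        )
        stat, p = logrank(df)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_textbook_example(self):
        # two groups with clear separation: statistic must be large
        df = pd.DataFrame(
            {
                "time": [1, 2, 3, 4, 10, 11, 12, 13],
                "event": [1] * 8,
                "group": ["a"] * 4 + ["b"] * 4,
            }
        )
        stat, p = logrank(df)
        assert stat > 3.84 and p < 0.05

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "time": rng.exponential(5, 20),
                "event": rng.integers(0, 2, 20),
                "group": ["a"] * 10 + ["b"] * 10,
            }
        )
        df2 = df.assign(group=df["group"].map({"a": "b", "b": "a"}))
        assert logrank(df)[0] == pytest.approx(logrank(df2)[0], rel=1e-9)

    def test_single_group_error(self):
        df = pd.DataFrame({"time": [1, 2], "event": [1, 1], "group": ["a", "a"]})
        with pytest.raises(ValueError):
            logrank(df)


def breslow_negloglik(beta, times, events, x):
    """Numeric oracle: Breslow partial log-likelihood for one covariate."""
    ll = 0.0
    for i in np.where(events == 1)[0]:
        at_risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return -ll


class TestCox:
    def test_matches_numeric_oracle_toy(self):
        # 6 records, distinct times (no ties: Breslow == Efron)
        times = np.array([1.0, 2.5, 3.1, 4.7, 5.2, 6.9])
        events = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        df = pd.DataFrame({"time": times, "event": events, "x": x})
        fit = cox_fit(df, ["x"])
        oracle = minimize_scalar(
            breslow_negloglik, args=(times, events, x), bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.summary.loc["x", "coef"] == pytest.approx(oracle.x, abs=1e-6)

    def test_planted_hr3_recovery(self):
        hits = 0
        n_sim = 100
        rng = np.random.default_rng(2)
        for _ in range(n_sim):
            x = rng.integers(0, 2, size=200)
            t = rng.exponential(1.0 / np.exp(np.log(3.0) * x))
            cens = rng.exponential(2.0, size=200)
            df = pd.DataFrame(
                {"time": np.minimum(t, cens), "event": (t <= cens).astype(int), "x": x}
            )
            fit = cox_fit(df, ["x"])
            if fit.converged and 2.0 <= fit.hazard_ratio("x") <= 4.5:
                hits += 1
        assert hits / n_sim >= 0.90

    def test_null_covariate_type_i(self):
        ok = 0
        n_sim = 100
        rng = np.random.default_rng(3)
        for _ in range(n_sim):
            t = rng.exponential(1.0, size=200)
            x = rng.normal(size=200)  # independent of survival
            df = pd.DataFrame({"time": t, "event": np.ones(200, dtype=int), "x": x})
            fit = cox_fit(df, ["x"])
            if abs(fit.z("x")) < 1.96:
                ok += 1
        assert ok / n_sim >= 0.93

    def test_sign_agrees_with_logrank_direction(self):
        rng = np.random.default_rng(4)
        for seed in range(10):
            x = rng.integers(0, 2, size=100)
            t = rng.exponential(1.0 / np.exp(0.8 * x))
            df = pd.DataFrame({"time": t, "event": np.ones(100, dtype=int), "x": x})
            fit = cox_fit(df, ["x"])
            km1 = np.median(t[x == 1])
            km0 = np.median(t[x == 0])
            assert (fit.summary.loc["x", "coef"] > 0) == (km1 < km0)

    def test_constant_covariate_error(self):
        df = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 1], "x": [1, 1, 1]})
        with pytest.raises(ValueError):
            cox_fit(df, ["x"])

    def test_multivariate_fit(self):
        rng = np.random.default_rng(5)
        n = 150
        x1 = rng.integers(0, 2, n)
        x2 = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(1.0 * x1 + 0.0 * x2))
        df = pd.DataFrame({"time": t, "event": np.ones(n, dtype=int), "a": x1, "b": x2})
        fit = cox_fit(df, ["a", "b"])
        assert fit.converged
        assert set(fit.summary.index) == {"a", "b"}


class TestGeneRanking:
    def test_hazard_protein_ranks_high(self):
        rng = np.random.default_rng(6)
        n_pat = 60
        patients = [f"P{i}" for i in range(n_pat)]
        risk = rng.normal(size=n_pat)
        t = rng.exponential(1.0 / np.exp(1.5 * risk))
        clinical = pd.DataFrame(
            {"patient_id": patients, "time": t, "event": np.ones(n_pat, dtype=int)}
        )
        # 30 proteins; protein 0 tracks the risk score
        mat = pd.DataFrame(
            rng.normal(size=(30, n_pat)), columns=[f"{p}_m1" for p in patients]
        )
        mat.iloc[0] += 3 * risk
        pmap = {f"{p}_m1": p for p in patients}
        ranks = rank_genes_by_survival(mat, clinical, pmap)
        top = ranks.head(3)["protein"].tolist()
        assert 0 in top
        assert ranks.iloc[0]["z"] > 0  # higher abundance -> shorter OS -> positive

    def test_permuted_survival_uncorrelated(self):
        rng = np.random.default_rng(7)
        n_pat = 40
        patients = [f"P{i}" for i in range(n_pat)]
        effect = np.linspace(-1, 1, 30)  # planted per-protein effects, unused
        clinical = pd.DataFrame(
            {
                "patient_id": patients,
                "time": rng.exponential(1, n_pat),
                "event": np.ones(n_pat, dtype=int),
            }
        )
        mat = pd.DataFrame(rng.normal(size=(30, n_pat)), columns=[f"{p}_m1" for p in patients])
        pmap = {f"{p}_m1": p for p in patients}
        ranks = rank_genes_by_survival(mat, clinical, pmap).set_index("protein")
        from scipy.stats import spearmanr

        rho = spearmanr(effect, ranks.loc[np.arange(30), "z"])[0]
        assert abs(rho) < 0.35


class TestSignatureScore:
    def test_zero_matrix(self):
        z = pd.DataFrame(np.zeros((10, 4)), index=[f"g{i}" for i in range(10)])
        out = signature_score(z, {"sig": [f"g{i}" for i in range(5)]})
        assert (out["sig"] == 0).all()

    def test_shifted_sample(self):
        z = pd.DataFrame(np.zeros((10, 3)), index=[f"g{i}" for i in range(10)], columns=list("abc"))
        z.loc[["g0", "g1", "g2"], "b"] = 2.0
        out = signature_score(z, {"sig": ["g0", "g1", "g2"]})
        assert out.loc["b", "sig"] == pytest.approx(2.0)
        assert out.loc["a", "sig"] == pytest.approx(0.0)

    def test_invariant_to_non_signature_genes(self):
        rng = np.random.default_rng(8)
        z = pd.DataFrame(rng.normal(size=(10, 3)), index=[f"g{i}" for i in range(10)])
        base = signature_score(z, {"sig": ["g0", "g1", "g2"]})
        z2 = z.copy()
        z2.iloc[5:] += 100
        assert signature_score(z2, {"sig": ["g0", "g1", "g2"]}).equals(base)

    def test_too_few_genes_absent(self):
        z = pd.DataFrame(np.zeros((10, 2)), index=[f"g{i}" for i in range(10)])
        out = signature_score(z, {"sig": ["g0", "g1"]})
        assert out["sig"].isna().all()


class TestMajorityCluster:
    def test_two_of_three(self):
        assign = pd.Series({"s1": 0, "s2": 0, "s3": 1})
        pmap = {"s1": "P", "s2": "P", "s3": "P"}
        out = majority_cluster_class(assign, pmap, target_clusters=(0, 2))
        assert out["P"] == "dominant"

    def test_exactly_half_is_other(self):
        assign = pd.Series({"s1": 2, "s2": 1})
        pmap = {"s1": "P", "s2": "P"}
        out = majority_cluster_class(assign, pmap, target_clusters=(0, 2))
        assert out["P"] == "other"

    def test_zero_of_four(self):
        assign = pd.Series({f"s{i}": 1 for i in range(4)})
        pmap = {f"s{i}": "P" for i in range(4)}
        assert majority_cluster_class(assign, pmap, (0, 2))["P"] == "other"

    def test_unmapped_samples_excluded(self):
        assign = pd.Series({"s1": 0, "s2": 0})
        out = majority_cluster_class(assign, {"s1": "P"}, (0,))
        assert list(out.index) == ["P"]
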