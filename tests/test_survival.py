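"""Cohort splitting, Cox screening, risk scores, log-rank, adjusted Cox."""

import numpy as np
import pandas as pd
import pytest

from cnacircuits.survival import (
    RiskModel,
    adjusted_cox,
    cox_screen,
    dichotomize,
    logrank,
    risk_scores,
    split_cohort,
)


def make_clinical(n, seed=0, lam=None, group=None, loghr=0.0):
    """Exponential survival with optional binary-group hazard and uniform
    censoring near 30%."""
    rng = np.random.default_rng(seed)
    base = np.log(2) / 800
    if lam is None:
        g = group if group is not None else np.zeros(n)
        lam = base * np.exp(loghr * g)
    t = rng.exponential(1 / lam)
    c = rng.uniform(0, 3000, size=n)
    return pd.DataFrame(
        {
            "time": np.minimum(t, c),
            "event": (t <= c).astype(int),
            "age": np.clip(rng.normal(50, 12, n).round(), 20, 85),
            "grade": rng.choice(["II", "III", "IV"], n),
            "gender": rng.choice(["male", "female"], n),
            "idh": rng.choice(["mutant", "wildtype"], n),
        },
        index=[f"P{i:03d}" for i in range(n)],
    )


class TestSplitCohort:
    def test_even_split(self):
        clin = make_clinical(100)
        train, test = split_cohort(clin, seed=1)
        assert abs(len(train) - len(test)) <= 4  # per-stratum rounding
        assert sorted(train + test) == sorted(clin.index)
        assert abs(clin.loc[train, "age"].mean() - clin.loc[test, "age"].mean()) < 2

    def test_single_gender_still_balances_age(self):
        clin = make_clinical(80, seed=2)
        clin["gender"] = "male"
        train, test = split_cohort(clin, seed=3)
        assert abs(clin.loc[train, "age"].mean() - clin.loc[test, "age"].mean()) < 2

    def test_deterministic_given_seed(self):
        clin = make_clinical(60)
        assert split_cohort(clin, seed=4) == split_cohort(clin, seed=4)
        assert split_cohort(clin, seed=4) != split_cohort(clin, seed=5)


class TestCoxScreen:
    def test_planted_hazard_gene_recovered(self):
        rng = np.random.default_rng(6)
        n = 200
        z = rng.normal(size=n)
        expr = pd.DataFrame(
            {"g_risk": 2 ** (z + 4), "g_null": rng.lognormal(2, 1, n)}
        ).T
        expr.columns = [f"P{i:03d}" for i in range(n)]
        lam = np.log(2) / 800 * np.exp(0.8 * z)
        clin = make_clinical(n, seed=7, lam=lam)
        res = cox_screen(expr, clin, ["g_risk", "g_null"])
        assert "g_risk" in set(res["gene"])
        row = res.set_index("gene").loc["g_risk"]
        assert row["beta"] > 0 and row["kind"] == "risk"

    def test_null_gene_pass_rate_near_alpha(self):
        rng = np.random.default_rng(9)
        n, m = 500, 100
        expr = pd.DataFrame(
            rng.lognormal(2, 1, size=(m, n)),
            index=[f"g{i}" for i in range(m)],
            columns=[f"P{i:03d}" for i in range(n)],
        )
        clin = make_clinical(n, seed=10)
        res = cox_screen(expr, clin, list(expr.index))
        rate = len(res) / m
        assert 0.0 <= rate <= 0.12  # ~5% expected, binomial slack

    def test_constant_gene_dropped(self):
        n = 50
        expr = pd.DataFrame(
            [[3.0] * n], index=["flat"], columns=[f"P{i:03d}" for i in range(n)]
        )
        res = cox_screen(expr, make_clinical(n), ["flat"])
        assert len(res) == 0

    def test_missing_gene_is_hard_error(self):
        n = 30
        expr = pd.DataFrame(
            [[1.0] * n], index=["g"], columns=[f"P{i:03d}" for i in range(n)]
        )
        with pytest.raises(KeyError):
            cox_screen(expr, make_clinical(n), ["absent"])


class TestRiskScores:
    def test_cancellation(self):
        betas = pd.Series([0.5, -0.5], index=["g1", "g2"])
        expr = pd.DataFrame([[2.0, 2.0], [2.0, 2.0]], index=["g1", "g2"],
                            columns=["s1", "s2"])
        scores = risk_scores(betas, expr, ["s1", "s2"])
        assert np.allclose(scores, 0.0)

    def test_zero_betas_zero_scores(self):
        betas = pd.Series([0.0, 0.0], index=["g1", "g2"])
        expr = pd.DataFrame(np.arange(6).reshape(2, 3), index=["g1", "g2"],
                            columns=list("abc"))
        assert np.allclose(risk_scores(betas, expr, list("abc")), 0.0)

    def test_single_gene_identity_on_transformed_scale(self):
        betas = pd.Series([1.0], index=["g"])
        expr = pd.DataFrame([[3.0, 7.0, 0.0]], index=["g"], columns=list("abc"))
        scores = risk_scores(betas, expr, list("abc"))
        assert np.allclose(scores, np.log2(np.array([3.0, 7.0, 0.0]) + 1))

    def test_additive_over_gene_partition(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.lognormal(1, 1, (4, 6)),
                            index=list("wxyz"), columns=[f"s{i}" for i in range(6)])
        betas = pd.Series(rng.normal(size=4), index=list("wxyz"))
        full = risk_scores(betas, expr, expr.columns)
        parts = (
            risk_scores(betas[:2], expr, expr.columns)
            + risk_scores(betas[2:], expr, expr.columns)
        )
        assert np.allclose(full, parts)

    def test_missing_gene_raises(self):
        betas = pd.Series([1.0], index=["absent"])
        expr = pd.DataFrame([[1.0]], index=["g"], columns=["s"])
        with pytest.raises(KeyError, match="absent"):
            risk_scores(betas, expr, ["s"])


class TestDichotomize:
    def test_median_threshold_and_tie_rule(self):
        train = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        test = pd.Series([2.6, 2.5], index=["hi", "lo"])
        labels, threshold = dichotomize(train, test)
        assert threshold == 2.5
        assert labels["hi"] == "high"
        assert labels["lo"] == "low"  # exactly at threshold -> low

    def test_frozen_threshold_order_invariant(self):
        train = pd.Series(np.arange(10, dtype=float), index=[f"t{i}" for i in range(10)])
        test = pd.Series([1.0, 8.0, 4.6], index=["a", "b", "c"])
        l1, _ = dichotomize(train, test)
        l2, _ = dichotomize(train, test.iloc[::-1])
        assert l1.loc[["a", "b", "c"]].equals(l2.loc[["a", "b", "c"]])

    def test_degenerate_model_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            dichotomize(pd.Series([2.0, 2.0, 2.0]))


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        clin = make_clinical(30, seed=11)
        dup = pd.concat([clin, clin.set_index(clin.index + "_copy")])
        groups = pd.Series(
            ["A"] * 30 + ["B"] * 30, index=list(dup.index)
        )
        stat, p = logrank(groups, dup)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_tally_on_small_fixture(self):
        # six subjects, all events; observed-minus-expected tally oracle
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.ones(6, dtype=int)
        grp = np.array(["A", "B", "A", "B", "A", "B"])
        clin = pd.DataFrame({"time": times, "event": events},
                            index=[f"s{i}" for i in range(6)])
        clin["age"] = 50
        groups = pd.Series(grp, index=clin.index)

        o_minus_e, var = 0.0, 0.0
        for t in np.unique(times):
            at_risk = times >= t
            d = ((times == t) & (events == 1)).sum()
            n = at_risk.sum()
            n_a = (at_risk & (grp == "A")).sum()
            d_a = ((times == t) & (events == 1) & (grp == "A")).sum()
            e_a = d * n_a / n
            o_minus_e += d_a - e_a
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        expected_stat = o_minus_e ** 2 / var

        stat, _ = logrank(groups, clin)
        assert stat == pytest.approx(expected_stat, rel=1e-9)

    def test_strong_effect_power(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            group = rng.integers(0, 2, size=200)
            clin = make_clinical(200, seed=seed + 100, group=group,
                                 loghr=np.log(3.0))
            groups = pd.Series(np.where(group == 1, "high", "low"), index=clin.index)
            _, p = logrank(groups, clin)
            hits += p < 0.05
        assert hits >= 38  # >= 95% power at HR 3

    def test_single_group_rejected(self):
        clin = make_clinical(10)
        with pytest.raises(ValueError, match="two groups"):
            logrank(pd.Series(["A"] * 10, index=clin.index), clin)


class TestAdjustedCox:
    def test_recovers_group_hazard_ratio(self):
        rng = np.random.default_rng(21)
        n = 400
        group = rng.integers(0, 2, size=n)
        clin = make_clinical(n, seed=22, group=group, loghr=np.log(2.0))
        groups = pd.Series(np.where(group == 1, "high", "low"), index=clin.index)
        res = adjusted_cox(groups, clin, clin[["age", "grade", "gender", "idh"]])
        assert 1.5 <= res["hr"] <= 2.7
        assert res["ci_low"] < res["hr"] < res["ci_high"]
        assert set(res["covariates"]) == {"age", "grade", "gender", "idh"}

    def test_null_group_ci_covers_one(self):
        covered = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 150
            clin = make_clinical(n, seed=seed + 50)
            groups = pd.Series(
                np.where(rng.integers(0, 2, n) == 1, "high", "low"), index=clin.index
            )
            res = adjusted_cox(groups, clin, None)
            covered += res["ci_low"] <= 1.0 <= res["ci_high"]
        assert covered >= 16  # ~95% nominal coverage, binomial slack

    def test_rank_deficient_covariates_error(self):
        clin = make_clinical(100, seed=30)
        groups = pd.Series(["high" if i % 2 else "low" for i in range(100)],
                           index=clin.index)
        cov = clin[["age"]].copy()
        cov["age_dup"] = cov["age"]
        with pytest.raises(ValueError, match="converge"):
            adjusted_cox(groups, clin, cov)


class TestRiskModelRoundTrip:
    def test_json_round_trip(self):
        model = RiskModel(pd.Series([0.4, -0.2], index=["g1", "g2"]), 1.25)
        back = RiskModel.from_dict(model.to_dict())
        assert back.threshold == model.threshold
        assert back.betas.equals(model.betas)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            RiskModel(pd.Series(dtype=float), 0.0)
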