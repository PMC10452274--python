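import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from icbench import (
    ClinicalTable,
    bh_adjust,
    cox_univariate,
    dichotomize_by_mean,
    logrank_test,
    paired_pre_on_test,
    spearman_correlation_matrix,
    stratify_response,
)
from icbench.benchmark import (
    NONRESPONDER,
    RESPONDER,
    UNEVALUABLE,
    test_categorical_score as fisher_exact_test,
    test_continuous_score as response_rank_test,
)
from icbench.errors import DegenerateDataError


def clinical(rows):
    return ClinicalTable(pd.DataFrame(rows))


def labels_for(groups):
    """Series mapping sample ids s0.. to responder/nonresponder labels."""
    out = {}
    for i, g in enumerate(groups):
        out[f"s{i}"] = g
    return pd.Series(out)


class TestStratifyResponse:
    @pytest.mark.parametrize(
        "category,pfs,expected",
        [
            ("CR", 7.0, RESPONDER),
            ("PR", 36.0, RESPONDER),
            ("SD", 8.0, RESPONDER),
            ("SD", 5.0, NONRESPONDER),
            ("PD", 12.0, NONRESPONDER),
            ("PD", None, NONRESPONDER),
            ("SD", 6.0, UNEVALUABLE),  # boundary is undefined by the rule
            ("SD", None, UNEVALUABLE),
            ("CR", None, UNEVALUABLE),  # rule needs PFS for CR/PR too
            ("NA", 10.0, UNEVALUABLE),
        ],
    )
    def test_rule(self, category, pfs, expected):
        table = clinical(
            [{"sample_id": "s1", "response_category": category,
              "pfs_months": pfs, "pfs_event": 1 if pfs is not None else None}]
        )
        assert stratify_response(table)["s1"] == expected


class TestContinuousTest:
    def test_perfect_separation_exact_p(self):
        scores = pd.Series([4, 5, 6, 1, 2, 3.0],
                           index=[f"s{i}" for i in range(6)])
        labels = labels_for([RESPONDER] * 3 + [NONRESPONDER] * 3)
        record = response_rank_test(scores, labels, direction="positive")
        assert record.p_value == pytest.approx(1 / 20)  # 1/C(6,3)
        assert record.auc == pytest.approx(1.0)
        assert (record.n_responder, record.n_nonresponder) == (3, 3)

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(3)
        aucs = []
        for _ in range(50):
            scores = pd.Series(rng.normal(size=40),
                               index=[f"s{i}" for i in range(40)])
            labels = labels_for([RESPONDER] * 20 + [NONRESPONDER] * 20)
            aucs.append(response_rank_test(scores, labels).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_orientation_symmetry(self, rng):
        scores = pd.Series(rng.normal(size=30),
                           index=[f"s{i}" for i in range(30)])
        labels = labels_for([RESPONDER] * 12 + [NONRESPONDER] * 18)
        pos = response_rank_test(scores, labels, direction="positive")
        neg = response_rank_test(-scores, labels, direction="negative")
        assert neg.p_value == pytest.approx(pos.p_value)
        assert neg.auc == pytest.approx(pos.auc)

    def test_empty_group_rejected(self, rng):
        scores = pd.Series(rng.normal(size=5),
                           index=[f"s{i}" for i in range(5)])
        labels = labels_for([RESPONDER] * 5)
        with pytest.raises(DegenerateDataError):
            response_rank_test(scores, labels)

    def test_auc_equals_pairwise_counting(self, rng):
        """AUC from the U statistic equals direct pairwise comparison
        counting (ties count half) across group sizes up to 10+10."""
        for n1 in range(1, 11):
            for n2 in range(1, 11):
                resp = rng.integers(0, 6, size=n1).astype(float)
                non = rng.integers(0, 6, size=n2).astype(float)
                scores = pd.Series(
                    np.concatenate([resp, non]),
                    index=[f"s{i}" for i in range(n1 + n2)],
                )
                labels = labels_for([RESPONDER] * n1 + [NONRESPONDER] * n2)
                record = response_rank_test(scores, labels)
                wins = sum(
                    1.0 if a > b else 0.5 if a == b else 0.0
                    for a in resp for b in non
                )
                assert record.auc == pytest.approx(wins / (n1 * n2), abs=1e-12)


def hypergeom_tail_oracle(table):
    """One-sided Fisher p for a 2x2 table by direct tail enumeration."""
    a, b = table[0]
    c, d = table[1]
    n, r1, c1 = a + b + c + d, a + b, a + c
    tail = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        if x >= a:
            tail += (
                comb(c1, x, exact=True)
                * comb(n - c1, r1 - x, exact=True)
                / comb(n, r1, exact=True)
            )
    return tail


class TestCategoricalTest:
    def to_series(self, table):
        cats, labels = [], []
        for j, lvl in enumerate(["x", "y"][: len(table[0])]):
            cats += [lvl] * (table[0][j] + table[1][j])
            labels += [RESPONDER] * table[0][j] + [NONRESPONDER] * table[1][j]
        idx = [f"s{i}" for i in range(len(cats))]
        return pd.Series(cats, index=idx), pd.Series(labels, index=idx)

    def test_diagonal_table_closed_form(self):
        cats, labels = self.to_series([[5, 0], [0, 5]])
        record = fisher_exact_test(cats, labels)
        assert record.p_value == pytest.approx(1 / 252)  # 1/C(10,5)

    def test_independent_table_not_significant(self):
        # one-sided tail of the balanced table: P(X >= 2) = 53/70
        cats, labels = self.to_series([[2, 2], [2, 2]])
        assert fisher_exact_test(cats, labels).p_value == pytest.approx(53 / 70)

    def test_all_small_2x2_tables_match_enumeration(self):
        for a, b, c, d in itertools.product(range(4), repeat=4):
            table = [[a, b], [c, d]]
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            if a + b + c + d > 12:
                continue
            cats, labels = self.to_series(table)
            record = fisher_exact_test(cats, labels)
            assert record.p_value == pytest.approx(
                hypergeom_tail_oracle(table), abs=1e-12
            )

    def test_2xk_exact_matches_scipy_on_2x2_margin(self):
        # 2x3 table with one empty column collapses to the 2x2 answer
        idx = [f"s{i}" for i in range(10)]
        cats = pd.Series(["x"] * 5 + ["y"] * 5, index=idx)
        labels = pd.Series([RESPONDER] * 5 + [NONRESPONDER] * 5, index=idx)
        rec22 = fisher_exact_test(cats, labels)
        cats3 = cats.replace({"y": "z"})  # still two observed levels
        rec2k = fisher_exact_test(cats3, labels)
        assert rec2k.p_value == pytest.approx(rec22.p_value, abs=1e-9)

    def test_single_level_rejected(self):
        idx = ["s0", "s1"]
        cats = pd.Series(["x", "x"], index=idx)
        labels = pd.Series([RESPONDER, NONRESPONDER], index=idx)
        with pytest.raises(DegenerateDataError):
            fisher_exact_test(cats, labels)


class TestPairedTest:
    def test_identical_pre_on_gives_p_one(self):
        pre = pd.Series([1.0, 2.0, 3.0, 4.0])
        record = paired_pre_on_test(pre, pre.copy())
        assert record.p_value == 1.0
        assert record.effect == 0.0

    def test_constant_shift_flagged_with_mean_change(self):
        pre = pd.Series([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="constant"):
            record = paired_pre_on_test(pre, pre + 1.0)
        assert record.effect == pytest.approx(1.0)
        assert np.isnan(record.p_value)
        assert record.flagged is not None

    def test_power_under_unit_shift(self):
        """delta=1, sigma=1, n=20: the closed-form power of the two-sided
        paired t at alpha=0.01 is 93.2%; the replicate rate must agree."""
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(200):
            pre = pd.Series(rng.normal(0, 1, 20))
            on = pre + rng.normal(1.0, 1.0, 20)
            if paired_pre_on_test(pre, on).p_value < 0.01:
                hits += 1
        assert 0.85 <= hits / 200 <= 0.99

    def test_too_few_pairs_rejected(self):
        pre = pd.Series([1.0, 2.0])
        with pytest.raises(DegenerateDataError):
            paired_pre_on_test(pre, pre + 0.5)


class TestDichotomize:
    def test_mean_split(self):
        groups = dichotomize_by_mean(pd.Series({"a": 1, "b": 2, "c": 3, "d": 10}))
        assert groups["d"] == "high"
        assert list(groups[["a", "b", "c"]]) == ["low"] * 3

    def test_symmetric_pair(self):
        groups = dichotomize_by_mean(pd.Series({"a": -1.0, "b": 1.0}))
        assert set(groups) == {"high", "low"}

    def test_affine_invariance(self, rng):
        scores = pd.Series(rng.normal(size=20),
                           index=[f"s{i}" for i in range(20)])
        base = dichotomize_by_mean(scores)
        pd.testing.assert_series_equal(
            base, dichotomize_by_mean(scores * 3.5 + 12.0)
        )

    def test_constant_rejected(self):
        with pytest.raises(DegenerateDataError):
            dichotomize_by_mean(pd.Series([2.0, 2.0, 2.0]))


def logrank_oracle(time, event, in_a):
    """Hand accumulation of the two-group log-rank O-E and variance."""
    order = np.argsort(time)
    time, event, in_a = time[order], event[order], in_a[order]
    o_minus_e, variance = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = ((time == t) & (event == 1)).sum()
        d_a = ((time == t) & (event == 1) & in_a).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e**2 / variance


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        time = pd.Series([2, 4, 6, 2, 4, 6.0], index=list("abcdef"))
        event = pd.Series([1, 1, 0, 1, 1, 0], index=list("abcdef"))
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=list("abcdef"))
        record = logrank_test(groups, time, event)
        assert record.statistic == pytest.approx(0.0, abs=1e-12)
        assert record.p_value == pytest.approx(1.0)

    def test_matches_hand_accumulation(self, rng):
        n = 30
        time = pd.Series(rng.exponential(10, n), index=[f"s{i}" for i in range(n)])
        event = pd.Series(rng.integers(0, 2, n), index=time.index)
        event.iloc[0] = 1
        groups = pd.Series(["g1"] * 15 + ["g2"] * 15, index=time.index)
        record = logrank_test(groups, time, event)
        oracle = logrank_oracle(
            time.to_numpy(), event.to_numpy(), (groups == "g1").to_numpy()
        )
        assert record.statistic == pytest.approx(oracle, abs=1e-10)

    def test_clear_separation_significant(self, rng):
        idx = [f"s{i}" for i in range(40)]
        time = pd.Series(
            np.concatenate([rng.exponential(2, 20), rng.exponential(40, 20)]),
            index=idx,
        )
        event = pd.Series([1] * 20 + [0] * 20, index=idx)
        groups = pd.Series(["g1"] * 20 + ["g2"] * 20, index=idx)
        assert logrank_test(groups, time, event).p_value < 0.01

    def test_no_events_rejected(self):
        time = pd.Series([1.0, 2.0], index=["a", "b"])
        event = pd.Series([0, 0], index=["a", "b"])
        groups = pd.Series(["g1", "g2"], index=["a", "b"])
        with pytest.raises(DegenerateDataError):
            logrank_test(groups, time, event)


def partial_loglik(beta, time, event, x):
    """Breslow partial log-likelihood (no ties in these fixtures)."""
    order = np.argsort(time)
    time, event, x = time[order], event[order], x[order]
    ll = 0.0
    for i in np.flatnonzero(event == 1):
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def test_beta_matches_grid_oracle(self, rng):
        n = 25
        x = rng.normal(size=n)
        time = rng.exponential(np.exp(-0.8 * x))
        event = np.ones(n)
        idx = [f"s{i}" for i in range(n)]
        record = cox_univariate(
            pd.Series(x, index=idx), pd.Series(time, index=idx),
            pd.Series(event, index=idx),
        )
        from scipy.optimize import minimize_scalar

        oracle = minimize_scalar(
            lambda b: -partial_loglik(b, time, event, x),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        ).x
        assert np.log(record.hr) == pytest.approx(oracle, abs=1e-4)

    def test_score_test_equals_logrank_for_binary_covariate(self, rng):
        """The log-rank chi-square is the Cox partial-likelihood score test
        at beta=0 for a binary covariate without ties."""
        n = 40
        idx = [f"s{i}" for i in range(n)]
        x = np.array([0.0] * 20 + [1.0] * 20)
        time = rng.exponential(np.exp(-0.5 * x))
        event = np.ones(n)
        groups = pd.Series(np.where(x == 1, "high", "low"), index=idx)
        lr = logrank_test(groups, pd.Series(time, index=idx),
                          pd.Series(event, index=idx))
        # score statistic U(0)^2 / I(0) computed directly
        order = np.argsort(time)
        ts, es, xs = time[order], event[order], x[order]
        u = fisher = 0.0
        for i in np.flatnonzero(es == 1):
            risk = ts >= ts[i]
            xbar = xs[risk].mean()
            u += xs[i] - xbar
            fisher += (xs[risk] ** 2).mean() - xbar**2
        assert lr.statistic == pytest.approx(u**2 / fisher, abs=1e-6)

    def test_constant_covariate_rejected(self):
        idx = ["a", "b", "c"]
        with pytest.raises(DegenerateDataError):
            cox_univariate(
                pd.Series([1.0, 1.0, 1.0], index=idx),
                pd.Series([1.0, 2.0, 3.0], index=idx),
                pd.Series([1, 1, 1], index=idx),
            )


class TestSpearmanMatrix:
    def test_diagonal_and_negation(self, rng):
        a = pd.Series(rng.normal(size=10))
        table = pd.DataFrame({"a": a, "b": -a, "c": rng.normal(size=10)})
        corr = spearman_correlation_matrix(table)
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(-1.0)
        assert corr.equals(corr.T)

    def test_closed_form_rank_triplet(self):
        table = pd.DataFrame({"u": [1.0, 2.0, 3.0], "v": [3.0, 1.0, 2.0]})
        corr = spearman_correlation_matrix(table)
        assert corr.loc["u", "v"] == pytest.approx(-0.5)  # 1 - 6*6/24

    def test_thin_columns_excluded_with_warning(self, rng):
        table = pd.DataFrame({
            "a": rng.normal(size=6),
            "b": [1.0, 2.0] + [np.nan] * 4,
        })
        with pytest.warns(UserWarning, match="excluding"):
            corr = spearman_correlation_matrix(table)
        assert list(corr.columns) == ["a"]


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        raw = np.sort(rng.uniform(size=25))
        adjusted = bh_adjust(raw)
        assert (adjusted >= raw - 1e-15).all()
        assert (np.diff(adjusted) >= -1e-15).all()
        assert (adjusted <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
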