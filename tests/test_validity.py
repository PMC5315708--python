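"""Group-comparison statistics, normalization, discrimination, correlations."""

import math

import numpy as np
import pandas as pd
import pytest

from scopemetrics import (
    discrimination,
    group_comparisons,
    metric_target_correlations,
    minmax_normalize,
    pearson_with_p,
    two_sample_t,
    validity_summary,
)


def pooled_t_oracle(a, b):
    """Hand-rolled pooled-variance two-sample t (textbook formula)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))


class TestTwoSampleT:
    def test_identical_samples(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.ok and res.t == 0.0 and res.p == 1.0

    def test_hand_computed_example(self):
        res = two_sample_t([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.674, abs=5e-4)
        assert res.df == 4
        assert res.p == pytest.approx(0.0213, abs=5e-5)

    def test_matches_pooled_formula_on_random_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.normal(0, 1, int(rng.integers(3, 12)))
            b = rng.normal(0.4, 1.6, int(rng.integers(3, 12)))
            res = two_sample_t(a, b)
            assert res.t == pytest.approx(pooled_t_oracle(a, b), rel=1e-12)
            assert res.df == len(a) + len(b) - 2

    def test_degenerate_zero_variance(self):
        assert not two_sample_t([0.0, 0.0], [0.0, 0.0]).ok

    def test_too_small_sample_flagged(self):
        assert not two_sample_t([1.0], [2.0, 3.0]).ok

    def test_missing_values_dropped(self):
        res = two_sample_t([1, 2, 3, np.nan], [4, 5, np.nan, 6])
        assert (res.n_a, res.n_b) == (3, 3)
        assert res.p == pytest.approx(0.0213, abs=5e-5)

    def test_welch_differs_under_variance_heterogeneity(self):
        a = [1.0, 1.1, 0.9, 1.05, 0.95]
        b = [2.0, 6.0, -1.0, 9.0, -3.0, 4.0]
        student = two_sample_t(a, b, variant="student")
        welch = two_sample_t(a, b, variant="welch")
        assert welch.df < student.df
        assert welch.p != student.p

    def test_label_permutation_approximates_student_p_at_moderate_n(self):
        # the permutation null of the t statistic converges to the t
        # distribution; at n=50 per group agreement is ~1e-2
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1.0, 50)
        b = rng.normal(0.45, 1.0, 50)
        res = two_sample_t(a, b)
        pool = np.concatenate([a, b])
        B = 20_000
        idx = np.argsort(rng.random((B, 100)), axis=1)
        perm = pool[idx]
        tperm = np.array([pooled_t_oracle(row[:50], row[50:]) for row in perm])
        p_perm = float(np.mean(np.abs(tperm) >= abs(res.t)))
        assert p_perm == pytest.approx(res.p, abs=0.015)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p, n, ok = pearson_with_p(x, 2 * x + 1)
        assert ok and r == pytest.approx(1.0) and p < 1e-30

    def test_perfect_negative(self):
        x = np.arange(5.0)
        r, _, _, _ = pearson_with_p(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # r = 10 / sqrt(10 * 14.8) = 0.82199...; p from t with df=3
        r, p, n, ok = pearson_with_p([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert r == pytest.approx(10 / math.sqrt(148), rel=1e-12)
        assert p == pytest.approx(0.0877, abs=5e-5)
        assert n == 5 and ok

    def test_zero_variance_flagged(self):
        assert not pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4])[3]

    def test_too_few_pairs_flagged(self):
        assert not pearson_with_p([1, 2], [3, 4])[3]

    def test_pairwise_complete(self):
        r, _, n, ok = pearson_with_p([1, 2, np.nan, 4, 5], [2, 4, 5, np.nan, 10])
        assert ok and n == 3


class TestMinmax:
    def test_arithmetic(self):
        out = minmax_normalize([2.0, 4.0, 6.0])
        assert np.array_equal(out.normalized, [0.0, 0.5, 1.0])
        assert (out.x_min, out.x_max) == (2.0, 6.0) and not out.degenerate

    def test_degenerate_constant(self):
        out = minmax_normalize([3.0, 3.0, 3.0])
        assert np.array_equal(out.normalized, [0.0, 0.0, 0.0]) and out.degenerate

    def test_attains_bounds(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            out = minmax_normalize(rng.normal(size=rng.integers(2, 30)))
            if not out.degenerate:
                assert out.normalized.min() == 0.0 and out.normalized.max() == 1.0


def make_table(metric_values):
    """Table with one new + one experienced surgeon per exercise.

    metric_values: {metric: (new_means, exp_means)} per-exercise values.
    """
    rows = []
    metrics = list(metric_values)
    n_ex = len(metric_values[metrics[0]][0])
    for i in range(n_ex):
        for group, which in (("new", 0), ("experienced", 1)):
            row = {"surgeon_id": f"{group}{i}", "group": group, "exercise_id": f"ex{i}"}
            for m in metrics:
                row[m] = metric_values[m][which][i]
            rows.append(row)
    return pd.DataFrame(rows)


class TestDiscrimination:
    def test_hand_worked_example(self):
        # new means {1,2,3}, experienced {3,4,5}: pooled bounds 1 and 5,
        # normalized means 0.25 vs 0.75, d = 0.5 exactly
        table = make_table({"a": ([1, 2, 3], [3, 4, 5])})
        (res,) = discrimination(table, metrics=["a"])
        assert res.d == 0.5
        assert np.array_equal(res.d_i, [0.5, 0.5, 0.5])

    def test_identical_metrics_tie(self):
        table = make_table(
            {"a": ([1, 2, 3], [3, 4, 5]), "b": ([1, 2, 3], [3, 4, 5])}
        )
        res = discrimination(table, metrics=["a", "b"])
        assert res[0].d == res[1].d
        assert res[0].pairwise_p["b" if res[0].metric == "a" else "a"] == 1.0

    def test_coincident_groups_rank_last(self):
        table = make_table(
            {"a": ([1, 2, 3], [3, 4, 5]), "flat": ([1, 2, 3], [1, 2, 3])}
        )
        res = discrimination(table, metrics=["a", "flat"])
        assert res[-1].metric == "flat" and res[-1].d == 0.0

    def test_affine_rescaling_invariance(self):
        new, exp = [0.3, 1.1, 0.7, 2.0], [1.4, 2.2, 1.9, 3.1]
        t1 = make_table({"a": (new, exp)})
        t2 = make_table({"a": ([7.0 * v - 2.0 for v in new], [7.0 * v - 2.0 for v in exp])})
        r1, = discrimination(t1, metrics=["a"])
        r2, = discrimination(t2, metrics=["a"])
        assert r1.d == pytest.approx(r2.d, rel=1e-12)
        assert r1.d_i == pytest.approx(r2.d_i, rel=1e-12)

    def test_exercise_order_invariance(self):
        table = make_table({"a": ([1, 5, 2], [2, 7, 4])})
        shuffled = table.sample(frac=1.0, random_state=4).reset_index(drop=True)
        r1, = discrimination(table, metrics=["a"])
        r2, = discrimination(shuffled, metrics=["a"])
        assert r1.d == r2.d and np.array_equal(r1.d_i, r2.d_i)

    def test_mostly_missing_metric_excluded(self, caplog):
        table = make_table({"a": ([1, 2, 3], [3, 4, 5]), "b": ([1, 2, 3], [3, 4, 5])})
        table.loc[table["exercise_id"] != "ex0", "b"] = np.nan
        import logging

        with caplog.at_level(logging.WARNING, "scopemetrics.validity"):
            res = discrimination(table, metrics=["a", "b"])
        assert [r.metric for r in res] == ["a"]
        assert "excluded" in caplog.text

    def test_needs_two_exercises(self):
        table = make_table({"a": ([1.0], [2.0])})
        with pytest.raises(ValueError):
            discrimination(table, metrics=["a"])


class TestGroupComparisons:
    def _cohort_table(self, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, n, mu in (("new", 6, 0.0), ("intermediate", 4, shift / 2), ("experienced", 5, shift)):
            for i in range(n):
                rows.append(
                    {"surgeon_id": f"{g}{i}", "group": g, "exercise_id": "ex0",
                     "m": rng.normal(mu, 1.0)}
                )
        return pd.DataFrame(rows)

    def test_means_and_sds_match_numpy(self):
        table = self._cohort_table(seed=3)
        gc = group_comparisons(table, "m", "ex0")
        for g in ("new", "intermediate", "experienced"):
            vals = table.loc[table["group"] == g, "m"].to_numpy()
            assert gc.means[g] == pytest.approx(vals.mean())
            assert gc.sds[g] == pytest.approx(vals.std(ddof=1))
            assert gc.ns[g] == len(vals)

    def test_single_surgeon_group_flagged(self):
        table = self._cohort_table()
        table = table[~((table.group == "intermediate") & (table.surgeon_id != "intermediate0"))]
        gc = group_comparisons(table, "m", "ex0")
        assert not gc.tests[("new", "intermediate")].ok
        assert gc.tests[("new", "experienced")].ok

    def test_missing_exercise_raises(self):
        with pytest.raises(ValueError):
            group_comparisons(self._cohort_table(), "m", "nope")


class TestCorrelationsAndSummary:
    def _table(self, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for ex in ("e1", "e2"):
            for g, n, skill in (("new", 6, 0.0), ("experienced", 6, 2.0)):
                for i in range(n):
                    ct = rng.normal(10 - 2 * skill, 1)
                    rows.append(
                        {"surgeon_id": f"{g}{i}", "group": g, "exercise_id": ex,
                         "cfrq": rng.normal(0.05 + 0.05 * skill, 0.01),
                         "cdur": rng.normal(2 - 0.5 * skill, 0.2),
                         "cint": rng.normal(20 - 6 * skill, 2),
                         "comp_time": ct, "overall_score": 100 - 8 * ct}
                    )
        return pd.DataFrame(rows)

    def test_result_count_bookkeeping(self):
        res = metric_target_correlations(self._table())
        assert len(res) == 2 * 3 * 2  # exercises x camera metrics x targets

    def test_constant_target_flagged(self):
        table = self._table()
        table["overall_score"] = 50.0
        res = metric_target_correlations(table, targets=["overall_score"])
        assert all(not c.ok for c in res)

    def test_generative_signs(self):
        res = metric_target_correlations(self._table(seed=1))
        for c in res:
            if c.target == "comp_time":
                assert (c.r < 0) == (c.metric == "cfrq")

    def test_validity_summary_declarations(self):
        vs = validity_summary(self._table(seed=2), metrics=("cfrq", "cdur", "cint"))
        assert vs["valid"].all()
        assert (vs["n_computable"] == 2).all()
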