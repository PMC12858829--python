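"""Group summaries, Welch/FDR inference and out-of-distribution flagging."""

import numpy as np
import pandas as pd
import pytest

from plexuq import (
    CohortTable,
    SubjectRecord,
    bh_fdr,
    compare_cohorts,
    iqr_flags,
    kl_divergence,
    summarize_groups,
    welch_t,
)


def brute_force_bh(pvalues, q):
    """Literal step-up definition: reject the largest k with p_(k) <= k q / n."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, n + 1):
        if p[order[k - 1]] <= k * q / n:
            k_star = k
    reject = np.zeros(n, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def make_table(groups):
    rows = []
    for label, values in groups.items():
        for i, v in enumerate(values):
            rows.append({"cohort": label, "subject_id": f"{label}{i}", "c_mi": v})
    return pd.DataFrame(rows)


class TestSummarizeGroups:
    def test_identical_values_collapse(self):
        df = make_table({"a": [0.3] * 5})
        out = summarize_groups(df, "cohort", "c_mi")
        row = out.iloc[0]
        assert row["mean"] == row.q1 == row.q3 == 0.3
        assert row.n == 5

    def test_linear_interpolation_quantiles(self):
        df = make_table({"a": [1, 2, 3, 4]})
        out = summarize_groups(df, "cohort", "c_mi").iloc[0]
        assert out.q1 == pytest.approx(1.75)
        assert out.q3 == pytest.approx(3.25)

    def test_groups_in_deterministic_label_order(self):
        df = make_table({"zeta": [1, 2], "alpha": [3, 4]})
        out = summarize_groups(df, "cohort", "c_mi")
        assert list(out["cohort"]) == ["alpha", "zeta"]

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError):
            summarize_groups(make_table({"a": [1]}), "nope", "c_mi")


class TestWelchT:
    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == 1.0

    def test_clear_shift_detected(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert p < 0.01
        assert t < 0

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 2, 12)
        t, df, p = welch_t(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_expected = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_expected = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        assert t == pytest.approx(t_expected, abs=1e-9)
        assert df == pytest.approx(df_expected, abs=1e-9)

    def test_pooled_coincidence_equal_variance_equal_n(self):
        """With equal n and equal sample variances, Welch == pooled Student t."""
        from scipy import stats

        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 10)
        b = a[::-1] + 0.7  # same variance, shifted
        t_w, _, p_w = welch_t(a, b)
        t_s, p_s = stats.ttest_ind(a, b, equal_var=True)[:2]
        assert t_w == pytest.approx(float(t_s), abs=1e-9)
        assert p_w == pytest.approx(float(p_s), abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestBhFdr:
    def test_single_p_unchanged(self):
        p_adj, reject = bh_fdr([0.03])
        assert p_adj[0] == pytest.approx(0.03)
        assert reject[0]

    def test_textbook_all_rejected(self):
        p_adj, reject = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_step_up(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 11))
        p = rng.random(n)
        _, reject = bh_fdr(p, q=0.05)
        assert np.array_equal(reject, brute_force_bh(p, 0.05))

    @pytest.mark.parametrize("seed", range(5))
    def test_adjusted_at_least_raw(self, seed):
        p = np.random.default_rng(seed).random(8)
        p_adj, _ = bh_fdr(p)
        assert (p_adj >= p - 1e-15).all()
        assert (p_adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestIqrFlags:
    def test_median_never_flagged(self):
        ref = np.arange(1, 101, dtype=float)
        for f in (0.0, 0.5, 1.5, 3.0):
            assert not iqr_flags(ref, [np.median(ref)], fence_multiplier=f)[0]

    def test_far_outlier_flagged(self):
        ref = np.arange(1, 101, dtype=float)
        flags = iqr_flags(ref, [500.0], fence_multiplier=1.5)
        assert flags[0]

    def test_zero_fence_is_literal_iqr_rule(self):
        ref = np.arange(1, 101, dtype=float)
        q1, q3 = np.quantile(ref, [0.25, 0.75])
        new = np.array([q1 - 0.1, q1 + 0.1, q3 - 0.1, q3 + 0.1])
        flags = iqr_flags(ref, new, fence_multiplier=0.0)
        assert list(flags) == [True, False, False, True]

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=50)
        new = rng.normal(size=10) * 5
        perm = rng.permutation(10)
        assert np.array_equal(iqr_flags(ref, new)[perm], iqr_flags(ref, new[perm]))

    def test_small_reference_rejected(self):
        with pytest.raises(ValueError):
            iqr_flags([1.0, 2.0, 3.0], [0.0])


class TestKlDivergence:
    def test_identical_samples_zero(self):
        x = np.linspace(0, 1, 50)
        assert kl_divergence(x, x) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(0, 1, 40)
        new = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), 40)
        assert kl_divergence(ref, new) >= 0.0

    def test_separated_gaussians_large(self):
        rng = np.random.default_rng(7)
        ref = rng.normal(0, 1, 1000)
        new = rng.normal(5, 1, 1000)
        assert kl_divergence(ref, new) > 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        ref, new = rng.normal(size=30), rng.normal(size=30)
        assert kl_divergence(ref, new) == pytest.approx(
            kl_divergence(rng.permutation(ref), rng.permutation(new)), abs=1e-12
        )

    def test_symmetric_variant_is_symmetric(self):
        rng = np.random.default_rng(2)
        ref, new = rng.normal(0, 1, 100), rng.normal(1, 1, 100)
        js_ab = kl_divergence(ref, new, symmetric=True)
        js_ba = kl_divergence(new, ref, symmetric=True)
        assert js_ab == pytest.approx(js_ba, abs=1e-12)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence([1.0] * 20, [1.0] * 20)


class TestCompareCohorts:
    def test_single_contrast_adjusted_equals_raw(self):
        rng = np.random.default_rng(0)
        df = make_table({"a": rng.normal(0, 1, 10), "b": rng.normal(2, 1, 10)})
        out = compare_cohorts(df, "c_mi", [("a", "b")])
        assert out.p_adj.iloc[0] == pytest.approx(out.p.iloc[0])

    def test_missing_group_rejected(self):
        df = make_table({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="not present"):
            compare_cohorts(df, "c_mi", [("a", "zz")])

    def test_reports_group_means(self):
        df = make_table({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = compare_cohorts(df, "c_mi", [("a", "b")])
        assert out.mean_a.iloc[0] == pytest.approx(2.0)
        assert out.mean_b.iloc[0] == pytest.approx(5.0)


class TestRecordsAndTable:
    def test_age_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SubjectRecord(
                subject_id="s",
                diagnosis="ASD",
                cohort="c",
                site="x",
                age_group="adult",
                uncertainty={"mi": 0.1},
                age=12,
            )

    def test_unique_ids_enforced(self):
        rec = SubjectRecord("s", "ASD", "c", "x", "adult", {"mi": 0.1})
        with pytest.raises(ValueError, match="unique"):
            CohortTable(records=[rec, rec])

    def test_frame_round_trip(self):
        records = [
            SubjectRecord(f"s{i}", "ASD", "c", "x", "adult", {"mi": 0.1 * i, "std": 0.2})
            for i in range(3)
        ]
        table = CohortTable(records=records)
        back = CohortTable.from_frame(table.to_frame())
        assert [r.subject_id for r in back.records] == ["s0", "s1", "s2"]
        assert back.records[2].uncertainty["mi"] == pytest.approx(0.2)
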