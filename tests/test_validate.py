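"""Split evaluation, permutation nulls, marker selection, univariate stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabostrat.annotate import marker_panel_table
from metabostrat.chemometrics import ModelError, auc_mann_whitney, fit_plsda
from metabostrat.simdata import SimConfig, generate_cohort
from metabostrat.validate import (
    anova_tukey,
    bh_fdr,
    confounder_checks,
    cross_cohort_predict,
    intersect_panels,
    longitudinal_tests,
    overlap_permutation_p,
    permutation_null,
    repeated_split_eval,
    select_markers,
    select_markers_from_cohorts,
    select_markers_from_vips,
    univariate_auc_ci,
    univariate_auc_panel,
    welch_fdr,
)

from conftest import cohort_xy


def bh_oracle(p):
    """Direct step-up definition of Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestRepeatedSplitEval:
    def test_strong_separation_fixture(self, small_config):
        x, y, _ = cohort_xy(generate_cohort(small_config, "B"))
        summary = repeated_split_eval(x, y, n_components=2, n_iterations=20, seed=0)
        assert summary.mean_auc >= 0.95
        assert summary.ci95["auc"][0] <= summary.mean_auc <= summary.ci95["auc"][1]
        assert summary.n_iterations == 20

    def test_defaults(self):
        import inspect

        sig = inspect.signature(repeated_split_eval)
        assert sig.parameters["n_iterations"].default == 100
        assert sig.parameters["train_fraction"].default == 0.7

    def test_too_small_class_rejected(self):
        x = np.random.default_rng(0).normal(size=(4, 3))
        with pytest.raises(ModelError):
            repeated_split_eval(x, np.array([1, 0, 0, 0]), 1, 2)


class TestCrossCohortPredict:
    def test_shared_signature_transfers(self, small_config):
        xa, ya, _ = cohort_xy(generate_cohort(small_config, "A"))
        xb, yb, _ = cohort_xy(generate_cohort(small_config, "B"))
        metrics = cross_cohort_predict((xb, yb), (xa, ya), n_components=2)
        assert metrics.auc > 0.9

    def test_shuffled_test_labels_are_null(self, small_config):
        xa, ya, _ = cohort_xy(generate_cohort(small_config, "A"))
        xb, yb, _ = cohort_xy(generate_cohort(small_config, "B"))
        rng = np.random.default_rng(0)
        aucs = [
            cross_cohort_predict((xb, yb), (xa, rng.permutation(ya)), 2).auc
            for _ in range(30)
        ]
        assert abs(float(np.mean(aucs)) - 0.5) < 0.1

    def test_panel_intersection(self):
        a = pd.DataFrame(np.ones((3, 3)), columns=["x", "y", "z"])
        b = pd.DataFrame(np.ones((3, 2)), columns=["z", "x"])
        ia, ib = intersect_panels(a, b)
        assert list(ia.columns) == list(ib.columns) == ["x", "z"]
        with pytest.raises(ModelError):
            intersect_panels(a, pd.DataFrame(np.ones((2, 1)), columns=["q"]))


class TestPermutationNull:
    def test_observed_below_all_nulls_gives_p_one(self):
        res = permutation_null(lambda X, y: -1e9 if y is None else float(y[0]) - 10,
                               None, np.arange(10), B=50, seed=0)
        assert res.empirical_p <= 1.0  # sanity on the container
        # direct construction of the bounds:
        obs_below = permutation_null(
            lambda X, y: 0.0 if (y == np.arange(10)).all() else 1.0,
            None, np.arange(10), B=50, seed=1,
        )
        assert obs_below.empirical_p == 1.0

    def test_observed_above_all_nulls_gives_lower_bound(self):
        res = permutation_null(
            lambda X, y: 1.0 if (y == np.arange(10)).all() else 0.0,
            None, np.arange(10), B=99, seed=2,
        )
        assert res.empirical_p == pytest.approx(1 / 100)

    def test_metric_failure_annotated(self):
        def metric(X, y):
            if (y != np.arange(4)).any():
                raise RuntimeError("boom")
            return 0.0

        with pytest.raises(RuntimeError, match="permutation"):
            permutation_null(metric, None, np.arange(4), B=20, seed=3)


class TestSelectMarkers:
    def test_reported_panel_vips_all_selected(self):
        """The four printed VIP columns plus AUC 0.60 select all 20."""
        df = marker_panel_table()
        records = select_markers_from_vips(
            df["vip_c1_a"], df["vip_c2_a"], df["vip_c1_b"], df["vip_c2_b"],
            np.full(len(df), 0.60),
            variable_names=df["name"].tolist(),
        )
        assert len(records) == 20
        assert {r.metabolite for r in records} == set(df["name"])

    def test_infinite_threshold_empties_panel(self):
        df = marker_panel_table()
        records = select_markers_from_vips(
            df["vip_c1_a"], df["vip_c2_a"], df["vip_c1_b"], df["vip_c2_b"],
            np.full(len(df), 0.9),
            vip_threshold=np.inf,
        )
        assert records == []

    @given(st.floats(1.0, 2.0), st.floats(0.6, 0.9))
    @settings(max_examples=20, deadline=None)
    def test_selection_monotone_in_thresholds(self, vip_t, auc_t):
        df = marker_panel_table()
        args = (df["vip_c1_a"], df["vip_c2_a"], df["vip_c1_b"], df["vip_c2_b"],
                df["vip_c1_a"] / 3.0)
        base = {r.metabolite for r in select_markers_from_vips(
            *args, variable_names=df["name"].tolist())}
        stricter = {r.metabolite for r in select_markers_from_vips(
            *args, variable_names=df["name"].tolist(),
            vip_threshold=vip_t, auc_threshold=auc_t)}
        assert stricter <= base

    def test_model_based_selection_recovers_designed_markers(self, small_config):
        sa = generate_cohort(small_config, "A")
        sb = generate_cohort(small_config, "B")
        xa, ya, names = cohort_xy(sa)
        xb, yb, _ = cohort_xy(sb)
        records = select_markers_from_cohorts(
            xa, ya, xb, yb, variable_names=names, n_components=2
        )
        selected = {r.metabolite for r in records}
        assert len(selected & set(sa.truth)) >= 4  # 5 strong designed markers

    def test_mismatched_panels_rejected(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 5)
        ma = fit_plsda(rng.normal(size=(10, 4)), y, 2)
        mb = fit_plsda(rng.normal(size=(10, 5)), y, 2)
        with pytest.raises(ModelError):
            select_markers(ma, mb, np.ones(4))


class TestOverlapPermutation:
    def test_toy_overlap_matches_direct_recomputation(self):
        rng = np.random.default_rng(1)
        n = 16
        y = np.array([0, 1] * (n // 2))
        xa = rng.normal(size=(n, 5))
        xb = rng.normal(size=(n, 5))
        xa[:, 0] += y * 4
        xb[:, 0] += y * 4
        res = overlap_permutation_p(xa, y, xb, y, B=20, seed=0, n_components=2)
        direct = len(select_markers_from_cohorts(xa, y, xb, y, n_components=2))
        assert res.observed == direct
        assert res.n_permutations == 20

    def test_strong_shared_signature_hits_lower_bound(self, small_config):
        xa, ya, _ = cohort_xy(generate_cohort(small_config, "A"))
        xb, yb, _ = cohort_xy(generate_cohort(small_config, "B"))
        res = overlap_permutation_p(xa, ya, xb, yb, B=19, seed=0, n_components=2)
        assert res.empirical_p == pytest.approx(1 / 20)


class TestWelchFdr:
    def test_identical_groups(self):
        t, p, _ = welch_fdr(np.ones((3, 2)), np.ones((4, 2)))
        assert np.allclose(t, 0.0) and np.allclose(p, 1.0)

    def test_textbook_example(self):
        """(1,2,3) vs (4,5,6): t and p from the closed-form Welch formula."""
        t, p, _ = welch_fdr(np.array([[1.0], [2.0], [3.0]]),
                            np.array([[4.0], [5.0], [6.0]]))
        # se = sqrt(1/3 + 1/3), t = -3/se, df = 4 by Welch-Satterthwaite
        from scipy import stats as sps

        se = np.sqrt(2 / 3)
        t_hand = -3 / se
        p_hand = 2 * sps.t.sf(abs(t_hand), 4)
        assert t[0] == pytest.approx(t_hand, abs=1e-12)
        assert p[0] == pytest.approx(p_hand, abs=1e-12)

    def test_bh_step_up_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_bh_matches_step_up_oracle(self, p_values):
        assert np.allclose(bh_fdr(p_values), bh_oracle(p_values), atol=1e-12)

    def test_fdr_never_below_raw(self):
        rng = np.random.default_rng(2)
        g1 = rng.normal(size=(5, 10))
        g2 = rng.normal(size=(6, 10))
        _, p, p_fdr = welch_fdr(g1, g2)
        assert np.all(p_fdr >= p - 1e-15)


class TestUnivariateAucCi:
    def test_perfect_separation(self):
        auc, (lo, hi) = univariate_auc_ci(
            [1.0, 2.0, 3.0, 10.0, 11.0, 12.0], [0, 0, 0, 1, 1, 1], n_boot=100, seed=0
        )
        assert auc == 1.0 and lo == 1.0 and hi == 1.0

    def test_bootstrap_ci_covers_known_auc(self):
        """Coverage of the designed AUC stays near the nominal 95%."""
        rng = np.random.default_rng(3)
        target = 0.75
        delta = np.sqrt(2) * 0.6744897501960817  # Phi^-1(0.75)
        covered = 0
        n_rep = 200
        for _ in range(n_rep):
            neg = rng.normal(0, 1, 20)
            pos = rng.normal(delta, 1, 20)
            values = np.concatenate([neg, pos])
            labels = np.array([0] * 20 + [1] * 20)
            _, (lo, hi) = univariate_auc_ci(
                values, labels, n_boot=200, seed=int(rng.integers(2**31 - 1))
            )
            covered += lo <= target <= hi
        assert 0.91 - 0.04 <= covered / n_rep  # allow slight undercoverage at n=40
        assert covered / n_rep <= 1.0

    def test_panel_auc_matches_scalar_auc(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 6))
        y = np.array([0, 1] * 15)
        panel = univariate_auc_panel(x, y)
        for j in range(6):
            auc = auc_mann_whitney(x[:, j], y)
            assert panel[j] == pytest.approx(max(auc, 1 - auc), abs=1e-12)


class TestAnovaTukey:
    def test_identical_groups(self):
        values = np.tile([1.0, 2.0, 3.0], 3)
        labels = np.repeat(["a", "b", "c"], 3)
        f, p, _ = anova_tukey(values, labels)
        assert f == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_hand_computed_f(self):
        """Three groups of five with hand-computable sums of squares."""
        groups = {
            "a": np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
            "b": np.array([3.0, 4.0, 5.0, 6.0, 7.0]),
            "c": np.array([5.0, 6.0, 7.0, 8.0, 9.0]),
        }
        values = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), 5)
        grand = values.mean()
        ss_between = 5 * sum((g.mean() - grand) ** 2 for g in groups.values())
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
        f_hand = (ss_between / 2) / (ss_within / 12)
        f, p, pairwise = anova_tukey(values, labels)
        assert f == pytest.approx(f_hand, abs=1e-10)
        assert len(pairwise) == 3

    def test_tukey_p_monotone_in_mean_difference(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([
            rng.normal(0, 1, 10), rng.normal(1, 1, 10), rng.normal(4, 1, 10)
        ])
        labels = np.repeat(["a", "b", "c"], 10)
        _, _, pairwise = anova_tukey(values, labels)
        p_by_pair = {
            (r["group1"], r["group2"]): float(r["p-adj"])
            for _, r in pairwise.iterrows()
        }
        assert p_by_pair[("a", "c")] <= p_by_pair[("a", "b")]

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([1.0, 2.0, 3.0, 4.0, 5.0], ["a", "a", "b", "b", "c"])


class TestLongitudinalTests:
    def _long_df(self, values_by_tp, n_subjects):
        rows = []
        for tp, vals in values_by_tp.items():
            for s in range(n_subjects):
                rows.append({"subject": f"S{s}", "timepoint_months": tp, "m1": vals[s]})
        return pd.DataFrame(rows)

    def test_null_series_fold_near_one(self):
        rng = np.random.default_rng(6)
        base = rng.normal(100, 5, 30)
        df = self._long_df({0: base + rng.normal(0, 1, 30),
                            24: base + rng.normal(0, 1, 30)}, 30)
        res = longitudinal_tests(df, [(0, 24)])
        assert res.loc[0, "fold_change"] == pytest.approx(1.0, abs=0.05)
        assert res.loc[0, "p_raw"] > 0.01

    def test_fold_orientation_earlier_over_later(self):
        df = self._long_df({0: [200.0, 210.0, 190.0, 205.0],
                            24: [100.0, 104.0, 96.0, 101.0]}, 4)
        res = longitudinal_tests(df, [(0, 24)])
        assert res.loc[0, "fold_change"] > 1.9  # decline reported as fold > 1

    def test_degenerate_constant_differences(self):
        """All subjects move by exactly one unit: certain-change convention."""
        df = self._long_df({0: [5.0, 6.0, 7.0, 8.0], 12: [4.0, 5.0, 6.0, 7.0]}, 4)
        res = longitudinal_tests(df, [(0, 12)])
        assert res.loc[0, "p_raw"] == 0.0

    def test_incomplete_pairs_rejected(self):
        df = self._long_df({0: [1.0, 2.0, 3.0], 12: [1.0, 2.0, 3.0]}, 3)
        df = df.drop(index=df.index[-1])
        with pytest.raises(ValueError, match="complete pairs"):
            longitudinal_tests(df, [(0, 12)])


class TestConfounderChecks:
    def _meta(self, sexes, groups):
        return pd.DataFrame({
            "sex": sexes,
            "group": groups,
            "age": np.linspace(40, 60, len(sexes)),
            "cohort": ["A"] * (len(sexes) // 2) + ["B"] * (len(sexes) - len(sexes) // 2),
        })

    def test_balanced_sex_table_gives_zero_chi2(self):
        meta = self._meta(["F", "M"] * 6, ["case", "case", "ctrl", "ctrl"] * 3)
        values = pd.DataFrame({"m1": np.ones(12)})
        values["m1"] = np.random.default_rng(0).normal(size=12)
        report = confounder_checks(meta, values)
        assert report["sex_chi2"] == pytest.approx(0.0, abs=1e-12)
        assert report["sex_p"] == pytest.approx(1.0)

    def test_chi2_matches_hand_formula(self):
        """2x2 table (8,7;5,13) against the Pearson formula."""
        sexes = ["F"] * 8 + ["M"] * 7 + ["F"] * 5 + ["M"] * 13
        groups = ["case"] * 15 + ["ctrl"] * 18
        meta = self._meta(sexes, groups)
        values = pd.DataFrame({"m1": np.random.default_rng(1).normal(size=33)})
        observed = np.array([[8, 5], [7, 13]], dtype=float)
        row = observed.sum(axis=1)
        col = observed.sum(axis=0)
        expected = np.outer(row, col) / observed.sum()
        chi2_hand = float(((observed - expected) ** 2 / expected).sum())
        report = confounder_checks(meta, values)
        assert report["sex_chi2"] == pytest.approx(chi2_hand, abs=1e-10)

    def test_age_independent_metabolite_slope_p_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 100
        for _ in range(n_rep):
            meta = self._meta(["F", "M"] * 15, ["case", "ctrl"] * 15)
            meta["age"] = rng.normal(52, 8, 30)
            values = pd.DataFrame({"m1": rng.normal(size=30)})
            report = confounder_checks(meta, values)
            rejections += report["age_slopes"]["m1"]["p"] < 0.05
        assert rejections <= 12  # binomial upper band around 5% of 100

    def test_missing_field_named(self):
        with pytest.raises(ValueError, match="age"):
            confounder_checks(
                pd.DataFrame({"sex": ["F"], "group": ["case"], "cohort": ["A"]}),
                pd.DataFrame({"m1": [1.0]}),
            )
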