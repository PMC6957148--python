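"""Cohort statistics: test oracles, selection behaviour, ROC identities."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pantex.cohort import (
    TextureCohortModel,
    backward_elimination_logistic,
    cohort_report,
    roc_analysis,
    two_group_test,
    univariate_screen,
)
from pantex.config import RunConfig
from pantex.features import FEATURE_NAMES


def make_table(case_values, control_values, feature="f"):
    rows = [{"subject_id": f"c{i}", "group": "case", feature: v}
            for i, v in enumerate(case_values)]
    rows += [{"subject_id": f"n{i}", "group": "control", feature: v}
             for i, v in enumerate(control_values)]
    return pd.DataFrame(rows)


class TestTwoGroupTest:
    def test_identical_groups_give_p_one(self):
        table = make_table([1, 2, 3], [1, 2, 3])
        res = two_group_test(table, "f", method="t")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_exact_mann_whitney_p(self):
        # U = 0; exact two-sided p = 2 / C(8,4) = 2/70
        table = make_table([1, 2, 3, 4], [10, 11, 12, 13])
        res = two_group_test(table, "f", method="mann_whitney")
        assert res.p_value == pytest.approx(2 / 70, rel=1e-9)

    def test_t_matches_pooled_closed_form(self, rng):
        # independent oracle: hand-computed pooled t and t CDF
        x = rng.normal(0, 1, size=7)
        y = rng.normal(0.5, 1, size=6)
        table = make_table(x, y)
        res = two_group_test(table, "f", method="t", variant="student")
        n1, n2 = len(x), len(y)
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        t_oracle = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), df=n1 + n2 - 2)
        assert res.statistic == pytest.approx(t_oracle, rel=1e-10)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-10)

    def test_zero_variance_both_groups_undefined(self):
        table = make_table([5, 5, 5], [5, 5, 5])
        res = two_group_test(table, "f", method="t")
        assert math.isnan(res.p_value)
        assert "zero variance" in res.message

    def test_requires_two_per_group(self):
        table = make_table([1], [1, 2, 3])
        with pytest.raises(ValueError, match=">= 2 subjects"):
            two_group_test(table, "f")

    def test_rejects_bad_group_labels(self):
        table = make_table([1, 2], [3, 4]).assign(group=["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="group labels"):
            two_group_test(table, "f")


class TestUnivariateScreen:
    def test_alpha_zero_selects_nothing(self, rng):
        table = make_table(rng.normal(size=20), rng.normal(1, 1, size=20))
        assert univariate_screen(table, alpha=0.0, features=("f",)) == []

    def test_large_effect_always_selected(self, rng):
        # d = 3 at n = 30/group: essentially certain detection
        table = make_table(rng.normal(3, 1, size=30), rng.normal(0, 1, size=30))
        table["noise"] = rng.normal(size=60)
        got = univariate_screen(table, alpha=0.05, features=("f", "noise"))
        assert "f" in got

    def test_preserves_column_order(self, rng):
        n = 40
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(2 * n)],
            "group": ["case"] * n + ["control"] * n,
            "b": np.r_[rng.normal(2, 1, n), rng.normal(0, 1, n)],
            "a": np.r_[rng.normal(2, 1, n), rng.normal(0, 1, n)],
        })
        assert univariate_screen(df, features=("b", "a")) == ["b", "a"]


class TestBackwardElimination:
    @staticmethod
    def simulated_cohort(rng, n=300, slope=1.0):
        a = rng.normal(size=2 * n)
        b = rng.normal(size=2 * n)
        c = rng.normal(size=2 * n)
        logits = slope * a
        y = rng.random(2 * n) < 1 / (1 + np.exp(-logits))
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(2 * n)],
            "group": np.where(y, "case", "control"),
            "a": a, "b": b, "c": c,
        })

    def test_p_remove_one_keeps_full_model(self, rng):
        table = self.simulated_cohort(rng)
        model = backward_elimination_logistic(table, ["a", "b", "c"], p_remove=1.01)
        assert set(model.retained) == {"a", "b", "c"}

    def test_p_remove_zero_empties_model(self, rng):
        table = self.simulated_cohort(rng)
        model = backward_elimination_logistic(table, ["a", "b", "c"], p_remove=0.0)
        assert model.retained == ()
        assert len(model.eliminated) == 3

    def test_single_significant_candidate_identity(self, rng):
        table = self.simulated_cohort(rng, n=400, slope=1.5)
        model = backward_elimination_logistic(table, ["a"], p_remove=0.10)
        assert model.retained == ("a",)
        term = model.terms[0]
        assert term.odds_ratio == pytest.approx(math.exp(term.coefficient), rel=1e-9)
        assert term.ci_low < term.odds_ratio < term.ci_high

    def test_null_recovery_large_n(self, rng):
        n = 2000
        table = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(2 * n)],
            "group": ["case"] * n + ["control"] * n,
            "a": rng.normal(size=2 * n),
        })
        model = backward_elimination_logistic(table, ["a"], p_remove=1.01)
        assert abs(math.log(model.terms[0].odds_ratio_per_sd)) < 0.1

    def test_slope_recovery_within_ten_percent(self, rng):
        n = 5000
        a = rng.normal(size=2 * n)
        y = rng.random(2 * n) < 1 / (1 + np.exp(-a))
        table = pd.DataFrame({
            "subject_id": range(2 * n),
            "group": np.where(y, "case", "control"),
            "a": a,
        })
        model = backward_elimination_logistic(table, ["a"], p_remove=1.01)
        assert model.terms[0].coefficient == pytest.approx(1.0, rel=0.1)

    def test_separation_is_flagged_not_fabricated(self):
        table = make_table([10.0, 11, 12, 13, 14, 15], [1.0, 2, 3, 4, 5, 6])
        model = backward_elimination_logistic(table, ["f"], p_remove=1.01)
        assert model.separation_flag

    def test_constant_candidate_rejected(self):
        table = make_table([1.0, 1, 1], [1.0, 1, 1])
        with pytest.raises(ValueError, match="constant"):
            backward_elimination_logistic(table, ["f"])

    def test_requires_candidates(self, rng):
        with pytest.raises(ValueError, match="at least one candidate"):
            backward_elimination_logistic(self.simulated_cohort(rng), [])


class TestROC:
    def test_perfect_separation(self):
        table = make_table([10, 11, 12], [1, 2, 3])
        res = roc_analysis(table, "f")
        assert res.auc == pytest.approx(1.0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.direction == "higher"

    def test_auc_equals_mann_whitney_u(self, rng):
        # trapezoid AUC must equal U/(n1*n2), midranks under ties
        for trial in range(20):
            x = np.round(rng.normal(0.5, 1, size=30), 1)  # rounding forces ties
            y = np.round(rng.normal(0, 1, size=25), 1)
            table = make_table(x, y)
            res = roc_analysis(table, "f")
            u = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
            auc_u = u / (len(x) * len(y))
            expected = auc_u if auc_u >= 0.5 else 1 - auc_u
            assert res.auc == pytest.approx(expected, abs=1e-12)

    def test_auc_matches_sklearn(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        x = rng.normal(1, 1, size=40)
        y = rng.normal(0, 1, size=35)
        table = make_table(x, y)
        res = roc_analysis(table, "f")
        ref = sklearn_metrics.roc_auc_score([1] * 40 + [0] * 35, np.r_[x, y])
        assert res.auc == pytest.approx(ref, abs=1e-12)

    def test_youden_cutoff_matches_exhaustive_scan(self):
        x = np.array([2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0])
        res = roc_analysis(make_table(x, y), "f")
        # oracle: scan all observed thresholds with rule case iff value >= t
        best_j = max(
            (x >= t).mean() + (y < t).mean() - 1 for t in np.unique(np.r_[x, y])
        )
        j_ours = res.sensitivity + res.specificity - 1
        assert j_ours == pytest.approx(best_j, abs=1e-12)
        assert (x >= res.optimal_cutoff).mean() == pytest.approx(res.sensitivity)

    def test_negated_feature_flips_direction_keeps_auc(self, rng):
        x = rng.normal(1, 1, size=25)
        y = rng.normal(0, 1, size=25)
        t1 = make_table(x, y)
        t2 = make_table(-x, -y)
        r1 = roc_analysis(t1, "f")
        r2 = roc_analysis(t2, "f")
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)
        assert {r1.direction, r2.direction} == {"higher", "lower"}

    def test_constant_feature_undefined(self):
        res = roc_analysis(make_table([1, 1, 1], [1, 1, 1]), "f")
        assert math.isnan(res.auc)
        assert "undefined" in res.message


class TestModelObjects:
    @staticmethod
    def feature_cohort(rng, n=25, shift=0.0):
        rows = []
        for grp, mu in (("case", shift), ("control", 0.0)):
            for i in range(n):
                feats = {f: rng.normal(mu if f == "variance" else 0, 1)
                         for f in FEATURE_NAMES}
                rows.append({"subject_id": f"{grp}{i}", "group": grp, **feats})
        return pd.DataFrame(rows)

    def test_report_lists_all_features_in_order(self, rng):
        table = self.feature_cohort(rng, shift=2.0)
        results = TextureCohortModel(table).fit()
        assert list(results.comparison_table["feature"]) == list(FEATURE_NAMES)

    def test_null_cohort_never_fabricates_model(self, rng):
        table = self.feature_cohort(rng, shift=0.0)
        results = TextureCohortModel(table).fit()
        assert set(results.logistic.retained) <= set(results.screened)

    def test_summary_mentions_retained_features(self, rng):
        table = self.feature_cohort(rng, n=40, shift=2.0)
        results = TextureCohortModel(table).fit()
        text = results.summary()
        assert "Multivariable logistic model" in text
        for feat in results.logistic.retained:
            assert feat in text

    def test_report_files_are_deterministic(self, rng, tmp_path):
        table = self.feature_cohort(rng, n=20, shift=1.0)
        cfg = RunConfig()
        p1 = cohort_report(table, cfg, out_dir=tmp_path / "a").save(tmp_path / "a")
        p2 = cohort_report(table, cfg, out_dir=tmp_path / "b").save(tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_missing_feature_column_rejected(self, rng):
        table = self.feature_cohort(rng).drop(columns=["variance"])
        with pytest.raises(ValueError, match="missing feature columns"):
            TextureCohortModel(table, features=FEATURE_NAMES)
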