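"""Statistical layer against independent oracles.

Every estimator is checked against a second, independent route: brute-force
Mann–Whitney pair counting for the AUC, an exhaustive threshold scan for the
Youden cutoff, pingouin's ANOVA-based ICC, and textbook formulas for
Pearson, Student's t and chi-square.
"""

import numpy as np
import pandas as pd
import pytest

from cctpipe import (
    GROUP_CONTROL, GROUP_VASOSPASM, SingleClassError, build_report,
    chi_square_table, icc_two_reader, pearson_r, roc_analysis, two_group_t,
)


def brute_force_auc(pos, neg):
    """All-pairs Mann-Whitney count, ties 1/2."""
    u = sum(1.0 if p > n else 0.5 if p == n else 0.0
            for p in pos for n in neg)
    return u / (len(pos) * len(neg))


def exhaustive_youden(pos, neg):
    """Best J over every 'positive iff score >= c' rule at observed scores."""
    scores = np.unique(np.concatenate([pos, neg]))
    best = max((np.mean(pos >= c) + np.mean(neg < c) - 1.0) for c in scores)
    return best


def _labels(n_pos, n_neg):
    return np.array([GROUP_VASOSPASM] * n_pos + [GROUP_CONTROL] * n_neg)


class TestIcc:
    def test_identical_readers_give_one(self):
        res = icc_two_reader([4.0, 5.0, 6.0, 7.0], [4.0, 5.0, 6.0, 7.0])
        assert res.icc == 1.0
        assert res.ci_low == res.ci_high == 1.0

    def test_matches_pingouin_on_random_tables(self, rng):
        import pingouin as pg
        for _ in range(50):
            a = rng.normal(6.0, 2.0, 41)
            b = a * rng.uniform(0.8, 1.2) + rng.normal(0, 1.0, 41)
            mine = icc_two_reader(a, b)
            df = pd.DataFrame({
                "targets": np.repeat(np.arange(41), 2),
                "raters": np.tile([0, 1], 41),
                "scores": np.column_stack([a, b]).ravel()})
            ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                     ratings="scores").set_index("Type")
            row = ref.loc["ICC(A,1)"]
            assert mine.icc == pytest.approx(row["ICC"], abs=1e-10)
            # pingouin prints the CI rounded to 2 decimals
            assert mine.ci_low == pytest.approx(row["CI95"][0], abs=0.006)
            assert mine.ci_high == pytest.approx(row["CI95"][1], abs=0.006)
            assert mine.ci_low <= mine.icc <= mine.ci_high

    def test_noise_degrades_agreement(self, rng):
        a = rng.normal(6.0, 2.0, 200)
        iccs = [icc_two_reader(a, a + rng.normal(0, s, 200)).icc
                for s in (0.1, 2.0, 20.0)]
        assert iccs[0] > 0.95 > iccs[1] > iccs[2]

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            icc_two_reader([1.0, 2.0], [1.0, 2.0])


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, r2, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_independent_series_near_zero(self, rng):
        x, y = rng.normal(size=(2, 4000))
        r, _, _ = pearson_r(x, y)
        assert abs(r) < 0.05

    def test_fixed_points_match_direct_formula(self, rng):
        x = rng.normal(5, 2, 10)
        y = 0.5 * x + rng.normal(0, 1, 10)
        r, r2, p = pearson_r(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_direct = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        assert r == pytest.approx(r_direct, abs=1e-12)
        from scipy import stats as sps
        t = r_direct * np.sqrt(8 / (1 - r_direct ** 2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 8), abs=1e-12)


class TestTwoGroupT:
    def test_identical_groups(self):
        res = two_group_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_pooled_formula(self, rng):
        x = rng.normal(5.0, 2.6, 19)
        y = rng.normal(6.4, 2.2, 22)
        res = two_group_t(x, y, variant="pooled")
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) \
            / (len(x) + len(y) - 2)
        t_direct = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
        assert res.t_statistic == pytest.approx(t_direct, abs=1e-12)

    def test_welch_differs_under_variance_imbalance(self, rng):
        x = rng.normal(0, 0.5, 10)
        y = rng.normal(0, 5.0, 40)
        assert (two_group_t(x, y, "pooled").p_value
                != two_group_t(x, y, "welch").p_value)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_group_t([1.0], [1.0, 2.0])


class TestChiSquare:
    def test_proportional_table_is_null(self):
        stat, p = chi_square_table(np.array([[10, 20], [5, 10]]))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_by_two_matches_hand_formula(self):
        # male/female split of a 19-vs-22 cohort
        table = np.array([[8, 11], [11, 11]])
        stat, p = chi_square_table(table)
        n = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / n
        stat_direct = ((table - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(stat_direct, abs=1e-12)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            chi_square_table(np.array([[0, 0], [3, 4]]))

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            chi_square_table(np.array([[1.5, 2.0], [3.0, 4.0]]))


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        res = roc_analysis(scores, _labels(3, 3)[::-1])
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert 3.0 < res.optimal_cutoff < 10.0

    def test_permuted_labels_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = _labels(1000, 1000)
        rng.shuffle(labels)
        assert roc_analysis(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_brute_force_mann_whitney(self, rng):
        """Exact equality with an exhaustive pair count, ties included."""
        for _ in range(50):
            n1, n0 = rng.integers(3, 31, size=2)
            # coarse rounding forces ties
            pos = np.round(rng.normal(1.0, 1.0, n1), 1)
            neg = np.round(rng.normal(0.0, 1.0, n0), 1)
            res = roc_analysis(np.concatenate([pos, neg]), _labels(n1, n0))
            assert res.auc == brute_force_auc(pos, neg)

    def test_youden_cutoff_matches_exhaustive_scan(self, rng):
        for _ in range(50):
            n1, n0 = rng.integers(3, 31, size=2)
            pos = np.round(rng.normal(1.0, 1.0, n1), 1)
            neg = np.round(rng.normal(0.0, 1.0, n0), 1)
            res = roc_analysis(np.concatenate([pos, neg]), _labels(n1, n0))
            j = res.sensitivity + res.specificity - 1.0
            assert j == pytest.approx(exhaustive_youden(pos, neg), abs=1e-12)
            # the reported cutoff achieves the reported operating point
            assert np.mean(pos >= res.optimal_cutoff) == pytest.approx(
                res.sensitivity)
            assert np.mean(neg < res.optimal_cutoff) == pytest.approx(
                res.specificity)

    def test_direction_less_for_flow_like_scores(self):
        # low score indicates disease; cutoff reported on the original scale
        pos = np.array([1.0, 1.5, 2.0])
        neg = np.array([4.0, 5.0, 6.0])
        res = roc_analysis(np.concatenate([pos, neg]), _labels(3, 3),
                           direction="less")
        assert res.auc == 1.0
        assert np.mean(pos <= res.optimal_cutoff) == 1.0
        assert np.mean(neg > res.optimal_cutoff) == 1.0

    def test_single_class_raises(self):
        with pytest.raises(SingleClassError):
            roc_analysis(np.arange(4.0), np.array([GROUP_CONTROL] * 4))

    def test_constant_scores_degenerate(self):
        res = roc_analysis(np.ones(6), _labels(3, 3))
        assert res.auc == 0.5
        assert "degenerate" in res.flags

    def test_ci_contains_auc(self, rng):
        scores = rng.normal(size=41)
        res = roc_analysis(scores, _labels(22, 19))
        assert res.auc_ci_low <= res.auc <= res.auc_ci_high


class TestBuildReport:
    @staticmethod
    def _cohort(rng, n_ctrl=19, n_vaso=22):
        from cctpipe import ALL_INDEXES
        rows = []
        for i in range(n_ctrl + n_vaso):
            vaso = i >= n_ctrl
            row = {"subject_id": f"S{i:03d}",
                   "group": GROUP_VASOSPASM if vaso else GROUP_CONTROL,
                   "gcs": int(rng.integers(3, 16)),
                   "fisher_grade": str(rng.choice(["I", "II", "III", "IV"])),
                   "cbv": rng.normal(4.0, 1.0), "cbf": rng.normal(30, 5),
                   "mtt": rng.normal(6, 1), "ttp": rng.normal(16, 2)}
            for name in ALL_INDEXES:
                base = rng.normal(6.4 if vaso else 5.0, 1.5)
                row[f"{name}_reader_a"] = base + rng.normal(0, 0.2)
                row[f"{name}_reader_b"] = base + rng.normal(0, 0.2)
                row[name] = 0.5 * (row[f"{name}_reader_a"]
                                   + row[f"{name}_reader_b"])
            rows.append(row)
        return pd.DataFrame(rows)

    def test_report_covers_all_indices(self, rng):
        report = build_report(self._cohort(rng))
        assert len(report["roc"]) == 11          # 7 CCTs + 4 perfusion
        assert len(report["icc"]) == 7
        assert len(report["correlations"]["ct_vs_xa"]) == 4
        assert report["n_control"] == 19 and report["n_vasospasm"] == 22
        assert "fisher_grade_chi_square" in report

    def test_single_group_cohort_reports_roc_errors(self, rng):
        report = build_report(self._cohort(rng, n_ctrl=10, n_vaso=0))
        assert all("error" in entry for entry in report["roc"].values())

    def test_report_is_deterministic(self, rng):
        import json
        cohort = self._cohort(rng)
        a = json.dumps(build_report(cohort), sort_keys=True)
        b = json.dumps(build_report(cohort.copy()), sort_keys=True)
        assert a == b
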