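"""Rank-based inference: Spearman, partial Spearman, Mann-Whitney U."""

import math

import numpy as np
import pytest
from scipy import stats

from emodyn import association_table, mann_whitney_u, partial_spearman, spearman

import oracles


class TestSpearman:
    def test_classic_d2_fixture(self):
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.coefficient == pytest.approx(0.8, abs=1e-12)
        assert res.coefficient == pytest.approx(
            oracles.spearman_d2([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]), abs=1e-12)
        assert res.n == 5 and res.df == 3

    @pytest.mark.parametrize("flip,expected", [(1, 1.0), (-1, -1.0)])
    def test_monotone_series(self, flip, expected):
        x = np.arange(10.0)
        res = spearman(x, flip * np.exp(x))
        assert res.coefficient == pytest.approx(expected)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(0, 5, 30).astype(float)
        res = spearman(x, y)
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert res.coefficient == pytest.approx(ref_rho, abs=1e-12)
        assert res.p_two_tailed == pytest.approx(ref_p, rel=1e-6)

    def test_symmetry_and_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        assert spearman(x, y).coefficient == pytest.approx(
            spearman(y, x).coefficient, abs=1e-15)
        assert spearman(np.exp(x), y).coefficient == pytest.approx(
            spearman(x, y).coefficient, abs=1e-15)

    def test_ci_brackets_coefficient_and_stays_in_range(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(size=12)
            y = 0.5 * x + rng.normal(size=12)
            res = spearman(x, y)
            assert -1 <= res.ci_low <= res.coefficient <= res.ci_high <= 1
            assert 0 < res.p_two_tailed <= 1

    def test_zero_rank_variance_reported_missing(self):
        res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert math.isnan(res.coefficient) and math.isnan(res.p_two_tailed)


class TestPartialSpearman:
    def test_empty_control_set_equals_simple(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 20))
        simple = spearman(x, y)
        part = partial_spearman(x, y, np.empty((20, 0)))
        assert part.coefficient == pytest.approx(simple.coefficient, abs=1e-12)
        assert part.df == simple.df

    def test_control_equal_to_y_removes_association(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        res = partial_spearman(x, y, y.reshape(-1, 1))
        assert abs(res.coefficient) < 1e-8

    def test_independent_control_changes_little(self):
        rng = np.random.default_rng(12)
        n = 1000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        c = rng.normal(size=n)
        simple = spearman(x, y).coefficient
        part = partial_spearman(x, y, c.reshape(-1, 1)).coefficient
        assert abs(part - simple) < 0.05

    def test_matches_matrix_inversion_oracle(self):
        rng = np.random.default_rng(21)
        checked = 0
        while checked < 50:
            n = int(rng.integers(6, 13))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            c = rng.normal(size=(n, 1))
            ranks = stats.rankdata
            corr = np.corrcoef(np.column_stack([ranks(x), ranks(y), ranks(c)]),
                               rowvar=False)
            if abs(np.linalg.det(corr)) < 1e-10:
                continue  # partial correlation undefined for this draw
            ours = partial_spearman(x, y, c).coefficient
            ref = oracles.partial_corr_matrix_inversion(ranks(x), ranks(y), ranks(c))
            assert ours == pytest.approx(ref, abs=1e-10)
            checked += 1

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(33)
        frame = pd.DataFrame({"x": rng.normal(size=30), "y": rng.normal(size=30),
                              "c": rng.normal(size=30)})
        ref = pingouin.partial_corr(frame, x="x", y="y", covar="c", method="spearman")
        ours = partial_spearman(frame.x, frame.y, frame[["c"]].to_numpy())
        assert ours.coefficient == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)

    def test_collinear_controls_rejected_by_name(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=(2, 20))
        c = rng.normal(size=20)
        controls = np.column_stack([c, 2 * c + 1])
        with pytest.raises(ValueError, match="collinear.*dup_a.*dup_b"):
            partial_spearman(x, y, controls, control_names=("dup_a", "dup_b"))

    def test_df_loses_one_per_control(self):
        rng = np.random.default_rng(14)
        x, y = rng.normal(size=(2, 30))
        c = rng.normal(size=(30, 2))
        res = partial_spearman(x, y, c)
        assert res.df == 30 - 2 - 2


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.u_statistic == 0.0
        assert res.p_two_tailed == pytest.approx(1 / 3, abs=1e-12)

    def test_exact_p_matches_full_enumeration(self):
        rng = np.random.default_rng(18)
        for _ in range(10):
            n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            pooled = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
            a, b = pooled[:n1], pooled[n1:]
            res = mann_whitney_u(a, b)
            u_ref, p_ref = oracles.mwu_exact_enumeration(list(a), list(b))
            assert res.u_statistic == pytest.approx(u_ref)
            assert res.p_two_tailed == pytest.approx(p_ref, abs=1e-12)

    def test_identical_samples_centre_u(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        res = mann_whitney_u(a, a)
        assert res.u_statistic == pytest.approx(len(a) ** 2 / 2)
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_normal_approximation_matches_scipy_with_ties(self):
        rng = np.random.default_rng(77)
        a = rng.integers(0, 8, 30).astype(float)
        b = rng.integers(2, 10, 25).astype(float)
        res = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.u_statistic == pytest.approx(ref.statistic)
        assert res.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_and_normal_agree_for_moderate_n(self):
        # untied n1=n2=8: the approximation should sit close to the exact law
        rng = np.random.default_rng(50)
        pooled = rng.choice(10_000, size=16, replace=False).astype(float)
        a, b = pooled[:8], pooled[8:]
        exact = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        approx = mann_whitney_u(a, b).p_two_tailed  # n=16 -> normal path here
        assert abs(exact - approx) < 0.03

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestAssociationTable:
    @pytest.fixture
    def features_frame(self):
        import pandas as pd

        rng = np.random.default_rng(30)
        n = 30
        sev = rng.integers(0, 28, n)
        frame = pd.DataFrame({
            "severity": sev,
            "f1": sev + rng.normal(scale=5, size=n),
            "f2": rng.normal(size=n),
            "f3": rng.normal(size=n),
            "f4": rng.normal(size=n),
        })
        return frame

    def test_simple_rows_one_per_feature(self, features_frame):
        table = association_table(features_frame, ["f1", "f2", "f3", "f4"])
        assert len(table) == 4
        assert set(table.columns) >= {"feature", "n", "coefficient", "ci_low",
                                      "ci_high", "p"}
        assert (table.n == 30).all()

    def test_control_set_adds_rows_with_reduced_df(self, features_frame):
        table = association_table(features_frame, ["f1", "f2", "f3", "f4"],
                                  control_sets=[(), ("f2",)])
        assert len(table) == 8
        simple = table[table.controls == ""]
        partial = table[table.controls == "f2"]
        assert (partial.df.to_numpy() == simple.df.to_numpy() - 1).all()

    def test_pairwise_deletion_reports_reduced_n(self, features_frame):
        features_frame.loc[[3, 17], "f1"] = np.nan
        table = association_table(features_frame, ["f1", "f2"])
        assert int(table.loc[table.feature == "f1", "n"].iloc[0]) == 28
        assert int(table.loc[table.feature == "f2", "n"].iloc[0]) == 30
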