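import numpy as np
import pandas as pd
import pytest

from oracles import brute_icc_a1_ci
from radrep.icc import (
    classify,
    icc_a1,
    icc_anova,
    icc_ci,
    icc_table,
    label_percentages,
    repeatability_report,
)


class TestPointEstimate:
    def test_hand_worked_matrix(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        ms_r, ms_c, ms_e = icc_anova(m)
        assert ms_r == pytest.approx(8.0)
        assert ms_c == pytest.approx(1.5)
        assert ms_e == pytest.approx(0.0, abs=1e-12)
        res = icc_a1(m)
        assert res.icc == pytest.approx(8.0 / 9.0)

    def test_perfect_agreement(self):
        m = np.column_stack([np.arange(6.0), np.arange(6.0)])
        res = icc_a1(m)
        assert res.icc == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)
        assert res.label == "repeatable"

    def test_null_monte_carlo(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(10_000, 2))
        assert abs(icc_a1(m).icc) < 0.05

    def test_degenerate_all_equal_flagged(self):
        res = icc_a1(np.full((5, 2), 3.0))
        assert not res.defined
        assert res.label == "not_repeatable"

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            icc_a1(np.array([[1.0, 2.0]]))


class TestInvariances:
    @pytest.fixture
    def matrix(self, rng):
        return rng.normal(size=(20, 2)) + rng.normal(size=(20, 1)) * 2.0

    def test_shift_invariance(self, matrix):
        assert icc_a1(matrix + 100.0).icc == pytest.approx(icc_a1(matrix).icc)

    def test_positive_scale_invariance(self, matrix):
        assert icc_a1(matrix * 5.0).icc == pytest.approx(icc_a1(matrix).icc)

    def test_column_swap_symmetry(self, matrix):
        assert icc_a1(matrix[:, ::-1]).icc == pytest.approx(icc_a1(matrix).icc)


class TestConfidenceInterval:
    def test_matches_brute_force_oracle_100_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            m = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1)) * rng.uniform(0.5, 3)
            res = icc_a1(m)
            icc_ref, lo_ref, hi_ref, ms_r, ms_c, ms_e = brute_icc_a1_ci(m)
            assert res.icc == pytest.approx(icc_ref, abs=1e-6)
            assert res.ci_low == pytest.approx(lo_ref, abs=1e-6)
            assert res.ci_high == pytest.approx(hi_ref, abs=1e-6)
            assert res.ms_r == pytest.approx(ms_r, abs=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(5, 30))
            m = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1)) * 2
            df = pd.DataFrame(
                {
                    "s": np.repeat(np.arange(n), 2),
                    "r": np.tile(["a", "b"], n),
                    "y": m.ravel(),
                }
            )
            row = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
            row = row[row["Type"] == "ICC(A,1)"].iloc[0]
            res = icc_a1(m)
            assert res.icc == pytest.approx(row["ICC"], abs=1e-6)
            lo, hi = row["CI95"]
            # pingouin prints its CI rounded to 2 decimals
            assert res.ci_low == pytest.approx(lo, abs=0.0051)
            assert res.ci_high == pytest.approx(hi, abs=0.0051)

    def test_ci_brackets_point_estimate(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 30))
            m = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1))
            res = icc_a1(m)
            assert res.ci_low <= res.icc <= res.ci_high

    def test_ci_narrows_with_n(self):
        # matched population: CI at n=5 wider than at n=50 (Monte-Carlo medians)
        rng = np.random.default_rng(11)

        def width(n, reps=60):
            ws = []
            for _ in range(reps):
                subj = rng.normal(size=(n, 1)) * 2.0
                m = subj + rng.normal(size=(n, 2)) * 0.5
                lo, hi = icc_ci(m)
                ws.append(hi - lo)
            return np.median(ws)

        assert width(5) > width(50)


class TestClassification:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (0.93, 0.99, "repeatable"),
            (0.91, 1.00, "repeatable"),
            (0.80, 0.95, "moderate"),
            (0.75, 0.91, "moderate"),
            (0.50, 0.95, "not_repeatable"),  # lower below 0.75
            (0.80, 0.89, "not_repeatable"),  # upper below 0.91
            (0.01, 0.90, "not_repeatable"),
            (-0.40, 0.95, "not_repeatable"),
            (0.909999, 0.99, "moderate"),  # just under the repeatable band
            (0.95, 1.0000001, "repeatable"),  # numeric overshoot clipped
            (float("nan"), float("nan"), "not_repeatable"),
        ],
    )
    def test_band_fixture_grid(self, lo, hi, expected):
        assert classify(lo, hi) == expected


class TestTableAPI:
    def _tables(self, rng, n=12, p=6, noise=0.2):
        subj = rng.normal(size=(n, 1)) * 2.0
        base = subj + rng.normal(size=(n, p)) * 0.1
        test = pd.DataFrame(base + rng.normal(size=(n, p)) * noise)
        retest = pd.DataFrame(base + rng.normal(size=(n, p)) * noise)
        test.columns = retest.columns = [f"original_firstorder_F{i}" for i in range(p)]
        return test, retest

    def test_perfectly_repeated_features_all_repeatable(self, rng):
        test, _ = self._tables(rng)
        table = icc_table(test, test.copy())
        assert (table["label"] == "repeatable").all()
        assert label_percentages(table)["repeatable"] == 100.0

    def test_independent_noise_near_zero_repeatable(self, rng):
        n, p = 40, 10
        cols = [f"original_glcm_F{i}" for i in range(p)]
        test = pd.DataFrame(rng.normal(size=(n, p)), columns=cols)
        retest = pd.DataFrame(rng.normal(size=(n, p)), columns=cols)
        table = icc_table(test, retest)
        assert (table["label"] == "repeatable").sum() == 0

    def test_pairwise_nan_dropping(self, rng):
        test, retest = self._tables(rng)
        test.iloc[0, 0] = np.nan
        table = icc_table(test, retest)
        assert table.iloc[0]["n_dropped"] == 1
        assert table.iloc[0]["n"] == len(test) - 1

    def test_min_subjects_enforced(self, rng):
        test, retest = self._tables(rng, n=6)
        test.iloc[:3, 0] = np.nan
        table = icc_table(test, retest, min_subjects=5)
        assert not table.iloc[0]["defined"]

    def test_report_structure(self, rng):
        test, retest = self._tables(rng)
        report = repeatability_report(icc_table(test, retest))
        assert set(report["overall"]) <= {"repeatable", "moderate", "not_repeatable"}
        assert report["n_features"] == 6
        assert "firstorder" in report["by_family"]
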