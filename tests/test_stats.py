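"""Coefficient-of-variation aggregations and ICC(2,1).

The ICC oracle is pingouin's ICC(A,1) row — an independent implementation of
the same two-way random-effects, absolute-agreement, single-measurement
model (point estimates to 1e-10; its CI bounds are published rounded to two
decimals, so those are compared at 5e-3).
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetmirror import (
    FetMirrorError,
    compare_methods,
    cov_percent,
    icc_2_1,
    icc_from_reader_table,
    inter_reader_cov,
    intra_reader_cov,
    read_reader_table,
    reliability_report,
    summarise_cov,
    validate_reader_table,
    write_reader_table,
)


def make_table(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "reader_id", "repeat", "method", "ctrl_suv_mean", "btv_cm3"]
    )


class TestCovPercent:
    def test_constant_series_is_zero(self):
        assert cov_percent([5.0] * 6) == 0.0

    def test_hand_formula(self):
        # sd([1,2,3]) = 1 (n-1 denominator), mean = 2 -> 50%
        assert cov_percent([1.0, 2.0, 3.0]) == pytest.approx(50.0)

    @settings(deadline=None, max_examples=50)
    @given(
        values=st.lists(st.floats(0.1, 100.0), min_size=2, max_size=10),
        c=st.floats(0.01, 50.0),
    )
    def test_scale_invariance(self, values, c):
        scaled = [v * c for v in values]
        assert cov_percent(scaled) == pytest.approx(cov_percent(values), abs=1e-8)

    def test_rejects_short_series_and_nonpositive_mean(self):
        with pytest.raises(ValueError, match="at least 2"):
            cov_percent([1.0])
        with pytest.raises(ValueError, match="mean"):
            cov_percent([0.0, 0.0])


class TestIntraReaderCov:
    def test_identical_repeats_give_zero_median(self):
        rows = [
            (p, r, j, "MI", 1.0, 4.0)
            for p in ("p1", "p2")
            for r in ("r1", "r2")
            for j in (1, 2, 3)
        ]
        covs = intra_reader_cov(make_table(rows), "ctrl_suv_mean", "MI")
        assert (covs["cov"] == 0.0).all()
        assert summarise_cov(covs)["overall"]["median"] == 0.0

    def test_hand_computed_cells(self):
        # patient A repeats {1,2,3} -> CoV 50%; patient B repeats {2,2,2} -> 0%
        rows = [("A", "r1", j, "MI", v, 1.0) for j, v in enumerate([1.0, 2.0, 3.0], 1)]
        rows += [("B", "r1", j, "MI", 2.0, 1.0) for j in (1, 2, 3)]
        covs = intra_reader_cov(make_table(rows), "ctrl_suv_mean", "MI")
        got = dict(zip(covs["patient_id"], covs["cov"]))
        assert got["A"] == pytest.approx(50.0)
        assert got["B"] == 0.0
        assert summarise_cov(covs)["overall"]["median"] == pytest.approx(25.0)

    def test_incomplete_repeat_set_names_cell(self):
        rows = [("A", "r1", j, "MI", 1.0, 1.0) for j in (1, 2, 3)]
        rows += [("A", "r2", j, "MI", 1.0, 1.0) for j in (1, 2)]
        with pytest.raises(ValueError, match="patient=A, reader=r2"):
            intra_reader_cov(make_table(rows), "ctrl_suv_mean", "MI")

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            intra_reader_cov(make_table([]), "ctrl_suv_mean", "MI")


class TestInterReaderCov:
    def test_agreement_gives_zero(self):
        rows = [("A", r, j, "MI", 2.0, 1.0) for r in ("r1", "r2", "r3") for j in (1, 2)]
        covs = inter_reader_cov(make_table(rows), "ctrl_suv_mean", "MI")
        assert (covs["cov"] == 0.0).all()

    def test_hand_computed_reader_means(self):
        # reader means {2, 2, 2, 4}: sd = 1, mean = 2.5 -> 40%
        rows = [("A", f"r{i}", 1, "MI", v, 1.0) for i, v in enumerate([2.0, 2.0, 2.0, 4.0], 1)]
        covs = inter_reader_cov(make_table(rows), "ctrl_suv_mean", "MI")
        assert covs["cov"].iloc[0] == pytest.approx(40.0)

    def test_single_reader_patient_rejected(self):
        rows = [("A", "r1", j, "MI", 1.0, 1.0) for j in (1, 2)]
        with pytest.raises(ValueError, match=">= 2 readers"):
            inter_reader_cov(make_table(rows), "ctrl_suv_mean", "MI")

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000), c=st.floats(0.1, 10.0))
    def test_scale_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        rows = [
            ("A", f"r{i}", j, "MI", float(rng.uniform(1, 3)), 1.0)
            for i in range(1, 4)
            for j in (1, 2)
        ]
        base = make_table(rows)
        scaled = base.assign(ctrl_suv_mean=base["ctrl_suv_mean"] * c)
        a = inter_reader_cov(base, "ctrl_suv_mean", "MI")["cov"].iloc[0]
        b = inter_reader_cov(scaled, "ctrl_suv_mean", "MI")["cov"].iloc[0]
        assert b == pytest.approx(a, abs=1e-8)


class TestICC:
    def test_perfect_agreement(self):
        col = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = icc_2_1(np.column_stack([col, col, col]))
        assert res.icc == pytest.approx(1.0)
        assert res.interpretation == "excellent"
        assert res.ci_low <= res.icc <= res.ci_high

    def test_constant_matrix_rejected(self):
        with pytest.raises(FetMirrorError, match="constant"):
            icc_2_1(np.ones((5, 3)))

    def test_incomplete_matrix_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            icc_2_1(X)

    def test_noisy_rater_matches_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(10, 2, size=6)
        X = np.column_stack([x, x + rng.normal(0, 0.5, size=6)])
        res = icc_2_1(X)
        oracle = _pingouin_icc_a1(X)
        assert res.icc == pytest.approx(oracle["icc"], abs=1e-10)

    @pytest.mark.parametrize("trial", range(5))
    def test_ci_matches_oracle_to_printed_precision(self, trial):
        rng = np.random.default_rng(100 + trial)
        n, k = rng.integers(4, 12), rng.integers(2, 6)
        X = rng.normal(5, 2, size=(n, k)) + rng.normal(0, 1, size=(n, 1))
        res = icc_2_1(X)
        oracle = _pingouin_icc_a1(X)
        assert res.icc == pytest.approx(oracle["icc"], abs=1e-10)
        assert res.ci_low == pytest.approx(oracle["ci"][0], abs=5e-3)
        assert res.ci_high == pytest.approx(oracle["ci"][1], abs=5e-3)

    def test_point_estimate_matches_oracle_on_100_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(3, 15))
            k = int(rng.integers(2, 8))
            X = rng.normal(0, 1, size=(n, k)) + rng.normal(0, 2, size=(n, 1))
            assert icc_2_1(X).icc == pytest.approx(_pingouin_icc_a1(X)["icc"], abs=1e-10)

    @pytest.mark.parametrize(
        "icc_value, expected",
        [(0.2, "poor"), (0.6, "moderate"), (0.8, "good"), (0.95, "excellent")],
    )
    def test_interpretation_bands(self, icc_value, expected):
        from fetmirror.stats import _interpret

        assert _interpret(icc_value) == expected


def _pingouin_icc_a1(X):
    import pingouin as pg

    n, k = X.shape
    df = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "ratings": X.ravel(),
        }
    )
    res = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="ratings")
    # the two-way random, absolute-agreement, single-rater row is labelled
    # ICC2 or ICC(A,1) depending on the pingouin version
    row = res[res["Type"].astype(str).str.match(r"ICC2$|ICC\(A,\s*1\)")]
    return {"icc": float(row["ICC"].iloc[0]), "ci": list(row["CI95"].iloc[0])}


class TestReaderTablePlumbing:
    def test_csv_round_trip(self, tmp_path):
        rows = [("A", "r1", j, m, 1.0 + j / 10, 4.0) for j in (1, 2) for m in ("MI", "gCS")]
        table = make_table(rows)
        write_reader_table(table, tmp_path / "t.csv")
        back = read_reader_table(tmp_path / "t.csv")
        pd.testing.assert_frame_equal(back, table, check_dtype=False)

    def test_duplicate_repeats_rejected(self):
        rows = [("A", "r1", 1, "MI", 1.0, 1.0), ("A", "r1", 1, "MI", 1.1, 1.0)]
        with pytest.raises(ValueError, match="duplicate repeat"):
            validate_reader_table(make_table(rows))

    def test_icc_from_reader_table_uses_repeat_means(self):
        rng = np.random.default_rng(3)
        rows = []
        means = {}
        for p in ("p1", "p2", "p3", "p4"):
            for r in ("r1", "r2"):
                vals = rng.uniform(1, 3, size=3)
                means[(p, r)] = vals.mean()
                rows += [(p, r, j + 1, "MI", v, 1.0) for j, v in enumerate(vals)]
        res = icc_from_reader_table(make_table(rows), "ctrl_suv_mean", "MI")
        X = np.array(
            [[means[(p, "r1")], means[(p, "r2")]] for p in ("p1", "p2", "p3", "p4")]
        )
        assert res.icc == pytest.approx(icc_2_1(X).icc)
        assert (res.n_targets, res.n_raters) == (4, 2)


class TestCompareMethods:
    def _mixed_table(self, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for p in [f"p{i}" for i in range(6)]:
            for r in ("r1", "r2", "r3"):
                for j in (1, 2, 3):
                    rows.append((p, r, j, "MI", 1.0, 4.0))  # no within-cell spread
                    rows.append(
                        (p, r, j, "gCS", float(rng.uniform(1.0, 1.3)), float(rng.uniform(3, 5)))
                    )
        return make_table(rows)

    def test_direction_and_significance_layout(self):
        table = self._mixed_table()
        cmp = compare_methods(table, "ctrl_suv_mean")
        assert cmp["intra_reader"]["overall_group"]["p_value"] < 0.05
        assert set(cmp["intra_reader"]["per_reader"]) == {"r1", "r2", "r3"}

    def test_degenerate_zero_differences_reported_not_raised(self):
        rows = [
            (p, r, j, m, 1.0, 4.0)
            for p in ("p1", "p2")
            for r in ("r1", "r2")
            for j in (1, 2)
            for m in ("MI", "gCS")
        ]
        cmp = compare_methods(make_table(rows), "ctrl_suv_mean")
        assert cmp["intra_reader"]["overall_group"]["p_value"] is None
        assert cmp["inter_reader"]["p_value"] is None

    def test_reliability_report_layout(self):
        report = reliability_report(self._mixed_table())
        for parameter in ("ctrl_suv_mean", "btv_cm3"):
            for method in ("MI", "gCS"):
                block = report[parameter][method]
                assert {"median", "min", "max", "n"} <= set(block["intra_reader"]["overall"])
                assert "icc" in block
            assert "comparison" in report[parameter]
        # MI table rows: all-zero intra-reader CoV, matching its determinism
        assert report["ctrl_suv_mean"]["MI"]["intra_reader"]["overall"]["median"] == 0.0
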