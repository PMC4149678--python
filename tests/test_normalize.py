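"""Normalization operators: IS/dry-weight, scalar, reference-ratio, QC baselines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from refnorm.core_data import IntensityMatrix, SampleRecord, ValidationError, build_layout
from refnorm.normalize import (
    FLAG_RLSC_FALLBACK,
    FLAG_ZERO_REFERENCE,
    assign_references,
    normalize_is_dryweight,
    normalize_scalar,
    normalize_to_reference,
    qc_median_correction,
    qc_rlsc,
)
from refnorm.simulate import SimulationConfig, simulate_experiment, truth_ratio_matrix
from tests.conftest import make_records


def matrix_of(rows: dict[str, list], metabolites: list[str], chain=()) -> IntensityMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=metabolites, dtype=float)
    return IntensityMatrix(df, list(chain))


class TestIsDryweight:
    def test_divides_by_is_times_dry_weight(self):
        m = matrix_of({"s1": [1000.0]}, ["m1"])
        rec = SampleRecord("s1", "B1", 1, "test", dry_weight_mg=2.5, is_intensity=500.0)
        out = normalize_is_dryweight(m, [rec]).matrix
        assert out.data.loc["s1", "m1"] == pytest.approx(0.8, abs=0)
        assert out.normalization_chain == [("is_dryweight", {})]

    def test_hand_oracle_arbitrary_values(self):
        # independent scalar arithmetic: 735.2 / (612.0 * 3.1)
        expected = 735.2 / (612.0 * 3.1)
        m = matrix_of({"s1": [735.2]}, ["m1"])
        rec = SampleRecord("s1", "B1", 1, "test", dry_weight_mg=3.1, is_intensity=612.0)
        out = normalize_is_dryweight(m, [rec]).matrix
        assert out.data.loc["s1", "m1"] == pytest.approx(expected, rel=1e-15)

    def test_zero_preserved_missing_preserved(self):
        m = matrix_of({"s1": [0.0, np.nan]}, ["m1", "m2"])
        rec = SampleRecord("s1", "B1", 1, "test", dry_weight_mg=3.0, is_intensity=100.0)
        out = normalize_is_dryweight(m, [rec]).matrix
        assert out.data.loc["s1", "m1"] == 0.0
        assert np.isnan(out.data.loc["s1", "m2"])

    def test_missing_metadata_names_sample(self, small_matrix):
        rec = SampleRecord("s1", "B1", 1, "test", dry_weight_mg=3.0, is_intensity=100.0)
        with pytest.raises(ValidationError, match="s2"):
            normalize_is_dryweight(small_matrix, [rec])


class TestScalar:
    @pytest.mark.parametrize(
        "statistic,row,expected",
        [
            ("total_sum", [1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4]),
            ("median", [1, 2, 3, 4], [0.4, 0.8, 1.2, 1.6]),
            ("total_sum", [5, np.nan, 15], [0.25, np.nan, 0.75]),
        ],
    )
    def test_row_division(self, statistic, row, expected):
        m = matrix_of({"s1": row}, [f"m{i}" for i in range(len(row))])
        out = normalize_scalar(m, statistic).matrix
        np.testing.assert_allclose(
            out.data.loc["s1"].to_numpy(), expected, rtol=1e-15
        )

    def test_nonpositive_statistic_names_sample(self):
        m = matrix_of({"s1": [0.0, 0.0]}, ["m1", "m2"])
        with pytest.raises(ValidationError, match="s1"):
            normalize_scalar(m, "total_sum")

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=30, deadline=None)
    def test_scale_equivariance(self, c):
        """Multiplying a sample by c > 0 leaves its scalar-normalized row unchanged."""
        base = matrix_of({"s1": [1.0, 2.0, 7.0]}, ["a", "b", "c"])
        scaled = matrix_of({"s1": [c, 2 * c, 7 * c]}, ["a", "b", "c"])
        for stat in ("total_sum", "median"):
            np.testing.assert_allclose(
                normalize_scalar(base, stat).matrix.values,
                normalize_scalar(scaled, stat).matrix.values,
                rtol=1e-9,
            )


class TestAssignReferences:
    def _records(self):
        rows = [("t%d" % i, "B1", i, "test") for i in range(1, 13)]
        rows[5] = ("ref1", "B1", 6, "reference")
        rows[11] = ("ref2", "B1", 12, "reference")
        return make_records(rows)

    def test_nearest_by_run_order(self):
        recs = self._records()
        assignment = assign_references(build_layout(recs), recs)
        assert assignment.references_for("t3") == ["ref1"]
        assert assignment.references_for("t11") == ["ref2"]

    def test_exact_tie_keeps_both(self):
        recs = self._records()
        assignment = assign_references(build_layout(recs), recs)
        assert assignment.references_for("t9") == ["ref1", "ref2"]

    def test_single_reference_serves_all(self):
        recs = make_records(
            [("a", "B1", 1, "test"), ("r", "B1", 2, "reference"), ("b", "B1", 3, "test")]
        )
        assignment = assign_references(build_layout(recs), recs)
        assert assignment.references_for("a") == ["r"]
        assert assignment.references_for("b") == ["r"]

    def test_reference_assigned_to_itself(self):
        recs = self._records()
        assignment = assign_references(build_layout(recs), recs)
        assert assignment.assigned["ref1"] == [("ref1", 0)]

    def test_batch_without_reference_rejected(self):
        recs = make_records([("a", "B1", 1, "test")])
        with pytest.raises(ValidationError, match="B1"):
            assign_references(build_layout(recs), recs)


class TestReferenceRatio:
    def _setup(self, values: dict[str, list], metabolites=("m1",)):
        recs = make_records(
            [
                ("t1", "B1", 1, "test"),
                ("r1", "B1", 2, "reference"),
                ("t2", "B1", 3, "test"),
                ("r2", "B1", 4, "reference"),
            ]
        )
        m = matrix_of(values, list(metabolites), chain=[("is_dryweight", {})])
        assignment = assign_references(build_layout(recs), recs)
        return m, assignment

    def test_simple_ratio(self):
        m, a = self._setup({"t1": [10.0], "r1": [5.0], "t2": [10.0], "r2": [5.0]})
        out = normalize_to_reference(m, a).matrix
        assert out.data.loc["t1", "m1"] == 2.0

    def test_tie_uses_mean_of_reference_intensities(self):
        # t2 is equidistant (1 run) from r1 and r2: 10 / mean(4, 6) = 2.0,
        # not the mean of ratios (2.083...)
        m, a = self._setup({"t1": [8.0], "r1": [4.0], "t2": [10.0], "r2": [6.0]})
        out = normalize_to_reference(m, a).matrix
        assert out.data.loc["t2", "m1"] == pytest.approx(2.0, abs=1e-15)

    def test_reference_rows_become_exactly_one(self):
        m, a = self._setup({"t1": [8.0], "r1": [4.0], "t2": [10.0], "r2": [6.0]})
        out = normalize_to_reference(m, a).matrix
        assert out.data.loc["r1", "m1"] == 1.0
        assert out.data.loc["r2", "m1"] == 1.0

    def test_zero_reference_flags_cell_missing(self):
        m, a = self._setup({"t1": [8.0], "r1": [0.0], "t2": [10.0], "r2": [6.0]})
        res = normalize_to_reference(m, a, policy="flag")
        assert np.isnan(res.matrix.data.loc["t1", "m1"])
        assert list(res.flags["flag"]) == [FLAG_ZERO_REFERENCE]
        assert res.flags.iloc[0]["sample_id"] == "t1"

    def test_drop_policy_removes_metabolite(self):
        m, a = self._setup(
            {"t1": [8.0, 1.0], "r1": [0.0, 2.0], "t2": [10.0, 3.0], "r2": [6.0, 4.0]},
            metabolites=("m1", "m2"),
        )
        res = normalize_to_reference(m, a, policy="drop")
        assert res.matrix.metabolite_ids == ["m2"]

    def test_chain_records_step(self):
        m, a = self._setup({"t1": [8.0], "r1": [4.0], "t2": [10.0], "r2": [6.0]})
        out = normalize_to_reference(m, a).matrix
        assert [s for s, _ in out.normalization_chain] == ["is_dryweight", "reference_ratio"]

    def test_warns_without_prior_is_dryweight_step(self):
        recs = make_records([("t1", "B1", 1, "test"), ("r1", "B1", 2, "reference")])
        m = matrix_of({"t1": [2.0], "r1": [1.0]}, ["m1"])  # raw chain
        a = assign_references(build_layout(recs), recs)
        with pytest.warns(UserWarning, match="is_dryweight"):
            normalize_to_reference(m, a)


class TestQcMedian:
    def _setup(self):
        recs = make_records(
            [
                ("q1", "B1", 1, "reference"),
                ("t1", "B1", 2, "test"),
                ("q2", "B1", 3, "reference"),
                ("q3", "B2", 4, "reference"),
                ("t2", "B2", 5, "test"),
                ("q4", "B2", 6, "reference"),
            ]
        )
        return recs

    def test_hand_example(self):
        # QC values of m1: batch1 {2, 4} (median 3), batch2 {6, 6} (median 6);
        # pooled global median of {2,4,6,6} = 5 -> factors 0.6 and 1.2;
        # a test value 10 in batch2 -> 10 / 1.2 = 8.333...
        recs = self._setup()
        m = matrix_of(
            {"q1": [2.0], "t1": [10.0], "q2": [4.0], "q3": [6.0], "t2": [10.0], "q4": [6.0]},
            ["m1"],
        )
        out = qc_median_correction(m, recs).matrix
        assert out.data.loc["t2", "m1"] == pytest.approx(10.0 / 1.2, rel=1e-12)
        assert out.data.loc["t1", "m1"] == pytest.approx(10.0 / 0.6, rel=1e-12)

    def test_equal_qc_values_are_identity(self):
        recs = self._setup()
        m = matrix_of(
            {"q1": [5.0], "t1": [7.0], "q2": [5.0], "q3": [5.0], "t2": [9.0], "q4": [5.0]},
            ["m1"],
        )
        out = qc_median_correction(m, recs).matrix
        np.testing.assert_allclose(out.values, m.values, rtol=1e-15)

    def test_single_batch_is_identity(self):
        recs = make_records(
            [("q1", "B1", 1, "reference"), ("t1", "B1", 2, "test"), ("q2", "B1", 3, "reference")]
        )
        m = matrix_of({"q1": [2.0], "t1": [10.0], "q2": [4.0]}, ["m1"])
        out = qc_median_correction(m, recs).matrix
        np.testing.assert_allclose(out.values, m.values, rtol=1e-15)

    def test_zero_qc_median_leaves_metabolite_unchanged_and_flagged(self):
        recs = self._setup()
        m = matrix_of(
            {"q1": [0.0], "t1": [10.0], "q2": [0.0], "q3": [0.0], "t2": [10.0], "q4": [0.0]},
            ["m1"],
        )
        res = qc_median_correction(m, recs)
        np.testing.assert_allclose(res.matrix.values, m.values, rtol=1e-15)
        assert "qc-median-undefined" in set(res.flags["flag"])


class TestQcRlsc:
    def _recs_and_matrix(self, qc_y, test_vals, qc_orders=(1, 5, 9), test_orders=(3, 7)):
        rows, values = [], {}
        for i, (o, y) in enumerate(zip(qc_orders, qc_y)):
            rows.append((f"q{i}", "B1", o, "reference"))
            values[f"q{i}"] = [y]
        for i, (o, v) in enumerate(zip(test_orders, test_vals)):
            rows.append((f"t{i}", "B1", o, "test"))
            values[f"t{i}"] = [v]
        recs = make_records(sorted(rows, key=lambda r: r[2]))
        m = matrix_of(values, ["m1"])
        return recs, m

    def test_constant_qc_signal_is_identity(self):
        recs, m = self._recs_and_matrix([5.0, 5.0, 5.0], [7.0, 11.0])
        out = qc_rlsc(m, recs, span=1.0, min_qc_points=3).matrix
        assert out.data.loc["t0", "m1"] == pytest.approx(7.0, rel=1e-12)
        assert out.data.loc["t1", "m1"] == pytest.approx(11.0, rel=1e-12)

    def test_linear_drift_hand_example(self):
        # QC 10, 8, 6 at orders 1, 5, 9: three collinear points, so the
        # degree-1 local fit is the exact line; fit(3) = 9, and a raw value
        # 18 corrects to 18/9 * median(10,8,6) = 16.
        recs, m = self._recs_and_matrix([10.0, 8.0, 6.0], [18.0, 7.0])
        out = qc_rlsc(m, recs, span=1.0, min_qc_points=3).matrix
        assert out.data.loc["t0", "m1"] == pytest.approx(16.0, rel=1e-10)

    def test_two_qc_points_span_one_equals_linear_interpolation(self):
        # independent oracle: division by np.interp between the two QC points
        recs, m = self._recs_and_matrix(
            [12.0, 4.0], [9.0, 5.0], qc_orders=(1, 9), test_orders=(3, 7)
        )
        out = qc_rlsc(m, recs, span=1.0, min_qc_points=2).matrix
        gmed = np.median([12.0, 4.0])
        for sid, order, raw in [("t0", 3, 9.0), ("t1", 7, 5.0)]:
            fit = np.interp(order, [1, 9], [12.0, 4.0])
            assert out.data.loc[sid, "m1"] == pytest.approx(raw / fit * gmed, rel=1e-10)

    def test_extrapolation_clamped_to_qc_range(self):
        recs, m = self._recs_and_matrix(
            [10.0, 6.0], [8.0], qc_orders=(3, 7), test_orders=(10,)
        )
        out = qc_rlsc(m, recs, span=1.0, min_qc_points=2).matrix
        # run order 10 is past the last QC (7): fit clamps to fit(7) = 6
        assert out.data.loc["t0", "m1"] == pytest.approx(8.0 / 6.0 * 8.0, rel=1e-10)

    def test_fallback_below_min_qc_points_matches_qc_median(self):
        recs, m = self._recs_and_matrix([10.0, 6.0], [8.0, 4.0], qc_orders=(1, 9))
        res = qc_rlsc(m, recs, span=1.0, min_qc_points=4)
        expected = qc_median_correction(m, recs).matrix
        np.testing.assert_allclose(res.matrix.values, expected.values, rtol=1e-12)
        assert FLAG_RLSC_FALLBACK in set(res.flags["flag"])


class TestPipelineCancellation:
    def test_exact_cancellation_without_noise(self):
        """Batch factors, IS response and dry weight cancel to machine precision."""
        cfg = SimulationConfig(
            seed=7, cv_base=0.0, cv_low_abundance=0.0, is_cv=0.0, drift_rate=0.0
        )
        matrix, records, truth = simulate_experiment(cfg)
        layout = build_layout(records)
        step1 = normalize_is_dryweight(matrix, records)
        assignment = assign_references(layout, records)
        step2 = normalize_to_reference(step1.matrix, assignment)
        target = truth_ratio_matrix(truth, layout)
        np.testing.assert_allclose(
            step2.matrix.values, target.values, rtol=1e-12, atol=0
        )

    def test_operators_preserve_shape_and_nonnegativity(self):
        cfg = SimulationConfig(seed=3, n_metabolites=20, n_batches=3)
        matrix, records, _ = simulate_experiment(cfg)
        layout = build_layout(records)
        assignment = assign_references(layout, records)
        outputs = [
            normalize_is_dryweight(matrix, records).matrix,
            normalize_scalar(matrix, "total_sum").matrix,
            normalize_scalar(matrix, "median").matrix,
            qc_median_correction(matrix, records).matrix,
            qc_rlsc(matrix, records).matrix,
        ]
        is_dw = outputs[0]
        outputs.append(normalize_to_reference(is_dw, assignment).matrix)
        for out in outputs:
            assert out.shape == matrix.shape
            vals = out.values
            assert not (vals[np.isfinite(vals)] < 0).any()
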