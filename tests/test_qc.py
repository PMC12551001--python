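"""Threshold derivation, sample verdicts, control checks, Levey-Jennings."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoscreen import synth
from neoscreen.errors import FormatError, InsufficientHistoryError
from neoscreen.genomic_io import VariantCall
from neoscreen.qc import (
    DEFAULT_RULES,
    QCRecord,
    Threshold,
    ThresholdSet,
    build_threshold_set,
    check_internal_control,
    derive_threshold,
    evaluate_sample,
    levey_jennings,
    read_qc_table,
    write_qc_table,
)


def quantile_oracle(values, q):
    """Independent linear-interpolation quantile on sorted order statistics."""
    xs = sorted(values)
    h = (len(xs) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def fence_oracle(values, direction, k=1.5):
    med = quantile_oracle(values, 0.5)
    iqr = quantile_oracle(values, 0.75) - quantile_oracle(values, 0.25)
    return med - k * iqr if direction == "lower_bound" else med + k * iqr


class TestDeriveThreshold:
    def test_zero_spread(self):
        assert derive_threshold([10, 10, 10, 10], "lower_bound", min_n=4) == 10

    def test_one_to_hundred_upper_fence(self):
        got = derive_threshold(list(range(1, 101)), "upper_bound")
        assert got == pytest.approx(50.5 + 1.5 * 49.5)  # 124.75

    def test_insufficient_history(self):
        with pytest.raises(InsufficientHistoryError):
            derive_threshold([1, 2, 3], "lower_bound")

    def test_tukey_fence_option(self):
        xs = list(range(1, 101))
        got = derive_threshold(xs, "upper_bound", fence="tukey")
        assert got == pytest.approx(75.25 + 1.5 * 49.5)

    @settings(derandomize=True, max_examples=150)
    @given(
        values=st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=8, max_size=200,
        ),
        direction=st.sampled_from(["lower_bound", "upper_bound"]),
    )
    def test_matches_independent_quantile_oracle(self, values, direction):
        got = derive_threshold(values, direction)
        assert got == pytest.approx(fence_oracle(values, direction), abs=1e-6)

    @settings(derandomize=True, max_examples=100)
    @given(
        values=st.lists(st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
                        min_size=8, max_size=50),
        k=st.floats(min_value=0.1, max_value=5.0),
        c=st.floats(min_value=-100, max_value=100),
        direction=st.sampled_from(["lower_bound", "upper_bound"]),
    )
    def test_affine_equivariance(self, values, k, c, direction):
        base = derive_threshold(values, direction)
        scaled = derive_threshold([k * x + c for x in values], direction)
        assert scaled == pytest.approx(k * base + c, abs=1e-6 * max(1, abs(k * base + c)))


class TestThresholdSet:
    def history(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return [
            QCRecord(f"S{i}", "B0", "2022-01-01",
                     {"PF_BASES": float(rng.uniform(4e9, 6e9))})
            for i in range(n)
        ]

    def test_fixed_defaults_v1_v2(self):
        ts1 = build_threshold_set(self.history(), DEFAULT_RULES["v1"], "v1")
        ts2 = build_threshold_set(self.history(), DEFAULT_RULES["v2"], "v2")
        assert ts1.thresholds["Q30_pct"].value == 85
        assert ts2.thresholds["Q30_pct"].value == 90
        assert ts1.thresholds["TARGET_BASES_30X_pct"].value == 93
        assert ts1.thresholds["MEAN_TARGET_COVERAGE"].value == 100
        assert ts1.thresholds["SELECTED_BASES_pct"].value == 40
        assert ts2.thresholds["SELECTED_BASES_pct"].value == 78
        assert ts1.thresholds["SNP_REFERENCE_BIAS"].value == 0.56
        assert ts1.thresholds["SNP_REFERENCE_BIAS"].direction == "upper_bound"

    def test_derived_matches_hand_computation(self):
        hist = self.history(seed=7)
        ts = build_threshold_set(hist, DEFAULT_RULES["v1"], "v1")
        values = [r.metrics["PF_BASES"] for r in hist]
        assert ts.thresholds["PF_BASES"].value == pytest.approx(
            fence_oracle(values, "lower_bound")
        )
        assert "derived from 20 samples" in ts.thresholds["PF_BASES"].provenance

    def test_json_round_trip(self, tmp_path):
        ts = build_threshold_set(self.history(), DEFAULT_RULES["v2"], "v2")
        ts.to_json(tmp_path / "t.json")
        back = ThresholdSet.from_json(tmp_path / "t.json")
        assert back.thresholds == ts.thresholds


def record(**metrics):
    base = {
        "PF_BASES": 5e9, "Q30_pct": 95.0, "TARGET_BASES_30X_pct": 97.0,
        "MEAN_TARGET_COVERAGE": 200.0, "SELECTED_BASES_pct": 85.0,
        "SNP_REFERENCE_BIAS": 0.50,
    }
    base.update(metrics)
    return QCRecord("S1", "B0", "2022-01-01", base)


@pytest.fixture(scope="module")
def v2_thresholds():
    rng = np.random.default_rng(1)
    hist = [QCRecord(f"H{i}", "B0", "2022-01-01",
                     {"PF_BASES": float(rng.uniform(4e9, 6e9))}) for i in range(20)]
    return build_threshold_set(hist, DEFAULT_RULES["v2"], "v2")


class TestEvaluateSample:
    def test_all_inside_passes(self, v2_thresholds):
        assert evaluate_sample(record(), v2_thresholds).status == "pass"

    def test_vip_failure_forces_repeat(self, v2_thresholds):
        verdict = evaluate_sample(record(Q30_pct=88.0), v2_thresholds)
        assert verdict.status == "repeat" and verdict.failed_metrics == ["Q30_pct"]

    def test_non_vip_failure_is_review(self, v2_thresholds):
        verdict = evaluate_sample(record(SELECTED_BASES_pct=70.0), v2_thresholds)
        assert verdict.status == "review"

    def test_boundary_value_passes(self, v2_thresholds):
        assert evaluate_sample(record(Q30_pct=90.0), v2_thresholds).status == "pass"
        assert evaluate_sample(record(SNP_REFERENCE_BIAS=0.56),
                               v2_thresholds).status == "pass"

    def test_missing_metric_fails(self, v2_thresholds):
        r = record()
        del r.metrics["MEAN_TARGET_COVERAGE"]
        verdict = evaluate_sample(r, v2_thresholds)
        assert verdict.status == "review"
        assert "MEAN_TARGET_COVERAGE" in verdict.failed_metrics

    def test_percentage_bounds_validated(self):
        with pytest.raises(FormatError):
            QCRecord("S1", "B0", "2022-01-01", {"Q30_pct": 130.0})

    def test_status_partition_and_vip_rule_randomized(self, v2_thresholds):
        """Every verdict is exactly one of pass/review/repeat and the VIP
        rule always holds."""
        from neoscreen.qc import VIP_METRICS

        rng = np.random.default_rng(99)
        for _ in range(300):
            metrics = {
                "PF_BASES": float(rng.uniform(1e9, 7e9)),
                "Q30_pct": float(rng.uniform(60, 100)),
                "TARGET_BASES_30X_pct": float(rng.uniform(60, 100)),
                "MEAN_TARGET_COVERAGE": float(rng.uniform(10, 400)),
                "SELECTED_BASES_pct": float(rng.uniform(10, 100)),
                "SNP_REFERENCE_BIAS": float(rng.uniform(0.3, 0.9)),
            }
            verdict = evaluate_sample(
                QCRecord("R", "B0", "2022-01-01", metrics), v2_thresholds
            )
            assert verdict.status in ("pass", "review", "repeat")
            vip_failed = any(m in VIP_METRICS for m in verdict.failed_metrics)
            assert (verdict.status == "repeat") == vip_failed
            assert (verdict.status == "pass") == (not verdict.failed_metrics)

    def test_raising_lower_threshold_only_converts_pass_to_fail(self, v2_thresholds):
        th = v2_thresholds.thresholds["SELECTED_BASES_pct"]
        raised = Threshold(th.metric, th.value + 10, th.direction, th.vip, th.provenance)
        rng = np.random.default_rng(5)
        for _ in range(100):
            value = float(rng.uniform(50, 100))
            if not th.passes(value):
                assert not raised.passes(value)


class TestCohortReplay:
    def test_planted_failure_plan_reproduced(self):
        records, expected = synth.make_qc_history(
            n_samples=520, failure_plan={1: 20, 2: 4, 3: 1}, seed=3
        )
        ts = build_threshold_set(records, DEFAULT_RULES["v1"], "v1")
        for rec, exp in zip(records, expected):
            verdict = evaluate_sample(rec, ts)
            assert verdict.status == exp["status"]
            assert sorted(verdict.failed_metrics) == exp["failed_metrics"]


class TestInternalControl:
    K1 = ("14", 1000, "G", "A")
    K2 = ("9", 2000, "G", "C")

    def control_calls(self, depth=100, genotype="het", include=("K1", "K2")):
        calls = []
        if "K1" in include:
            calls.append(VariantCall(*self.K1, genotype, depth,
                                     (depth // 2, depth - depth // 2), 15.0, "H12"))
        if "K2" in include:
            calls.append(VariantCall(*self.K2, "het", depth,
                                     (depth // 2, depth - depth // 2), 15.0, "H12"))
        return calls

    def expected(self):
        return {self.K1: "het", self.K2: "het"}

    def test_both_found_passes(self):
        check = check_internal_control(self.control_calls(), self.expected())
        assert check.overall_pass
        assert all(v.allele_depth_fraction == pytest.approx(0.5)
                   for v in check.variants)

    def test_missing_variant_fails(self):
        check = check_internal_control(self.control_calls(include=("K1",)),
                                       self.expected())
        assert not check.overall_pass
        missing = [v for v in check.variants if v.key == self.K2]
        assert missing and not missing[0].found

    def test_wrong_genotype_fails(self):
        check = check_internal_control(self.control_calls(genotype="hom_alt"),
                                       self.expected())
        assert not check.overall_pass
        assert not [v for v in check.variants if v.key == self.K1][0].genotype_match

    def test_low_depth_fails(self):
        check = check_internal_control(self.control_calls(depth=10), self.expected())
        assert not check.overall_pass


class TestLeveyJennings:
    def test_constant_series_no_flags(self):
        s = levey_jennings([(f"B{i}", 5.0) for i in range(10)], "depth")
        assert s.sd == 0 and s.flagged == []

    def test_injected_outlier_flagged(self):
        rng = np.random.default_rng(4)
        values = [("B%d" % i, float(rng.normal(100, 2))) for i in range(30)]
        arr = np.array([v for _, v in values])
        values.append(("B30", float(arr.mean() + 5 * arr.std(ddof=1))))
        s = levey_jennings(values, "depth")
        assert s.flagged == ["B30"]

    def test_single_point_no_bands(self):
        s = levey_jennings([("B0", 5.0)], "depth")
        assert s.mean is None and s.bands() is None and s.flagged == []

    def test_window_restricts_band_scope(self):
        points = [(f"B{i}", 1.0) for i in range(5)] + [(f"B{i}", 9.0) for i in range(5, 10)]
        s = levey_jennings(points, "depth", window=5)
        assert s.mean == pytest.approx(9.0) and s.sd == 0


class TestTableIO:
    def test_round_trip(self, tmp_path):
        records, _ = synth.make_qc_history(20, {1: 2}, seed=8)
        path = tmp_path / "qc.tsv"
        write_qc_table(records, path)
        back = read_qc_table(path)
        assert [r.sample_id for r in back] == [r.sample_id for r in records]
        for a, b in zip(back, records):
            for m, v in b.metrics.items():
                assert a.metrics[m] == pytest.approx(v, rel=1e-5)

    def test_missing_id_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample\tQ30_pct\nS1\t95\n")
        with pytest.raises(FormatError):
            read_qc_table(path)
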