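import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirspot import preprocess, tables
from mirspot.errors import ConfigurationError, ConsistencyError, QualificationError
from mirspot.preprocess import DetectionThresholds
from mirspot.simulate import generate_array_experiment

from conftest import small_config


def nearest_rank_p95(values):
    """Independent oracle: smallest value v with #(x <= v) >= 0.95 n."""
    values = list(values)
    n = len(values)
    for v in sorted(values):
        if sum(1 for x in values if x <= v) >= 0.95 * n:
            return v
    raise AssertionError("unreachable")


class TestBackgroundAndLog2:
    @pytest.mark.parametrize("fg,bg,expected", [
        (500.0, 100.0, 400.0), (100.0, 100.0, 0.0), (50.0, 100.0, -50.0)])
    def test_background_subtraction(self, fg, bg, expected):
        assert preprocess.subtract_background(fg, bg) == expected

    @pytest.mark.parametrize("x,floor,expected", [
        (1024.0, 1.0, 10.0), (-50.0, 1.0, 0.0), (4.0, 4.0, 2.0)])
    def test_log2_with_floor(self, x, floor, expected):
        assert preprocess.log2_transform(x, floor) == pytest.approx(expected)

    def test_floor_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            preprocess.log2_transform(5.0, 0.0)


class TestTpt95:
    def test_constant_negatives(self):
        assert preprocess.compute_tpt95([1024.0] * 100) == pytest.approx(10.0)

    def test_integers_1_to_100(self):
        expected = math.log2(95)
        assert preprocess.compute_tpt95(np.arange(1.0, 101.0)) == pytest.approx(expected)

    def test_empty_is_error(self):
        with pytest.raises(ConfigurationError):
            preprocess.compute_tpt95([])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.1, max_value=1e6,
                              allow_nan=False, allow_infinity=False),
                    min_size=1, max_size=200))
    def test_matches_nearest_rank_oracle(self, values):
        expected = math.log2(max(nearest_rank_p95(values), 1.0))
        assert preprocess.compute_tpt95(values) == pytest.approx(expected)

    def test_lognormal_analytic_quantile(self):
        """Large-sample TPT95 approaches the generating 95% quantile."""
        rng = np.random.default_rng(123)
        mu, sigma = 6.0, 0.5  # log2-scale parameters
        negatives = np.exp2(rng.normal(mu, sigma, 10_000))
        analytic = mu + 1.6448536269514722 * sigma
        assert preprocess.compute_tpt95(negatives) == pytest.approx(analytic, abs=0.05)


class TestNormalizationProbeSelection:
    def thresholds(self, arrays, value=5.0):
        return DetectionThresholds(pd.Series(value, index=arrays))

    def test_exact_margin_is_excluded(self):
        m = tables.IntensityMatrix(
            pd.DataFrame({"a1": [6.0, 9.0], "a2": [8.0, 9.0]},
                         index=["edge", "good"]), "log2")
        probes = preprocess.select_normalization_probes(m, self.thresholds(["a1", "a2"]))
        assert probes == frozenset({"good"})

    def test_exact_sd_max_is_excluded(self):
        # SD of (7, 9.5) = 1.7678 > 1.25; SD of (8, 8.1) fine
        m = tables.IntensityMatrix(
            pd.DataFrame({"a1": [7.0, 8.0], "a2": [9.5, 8.1]},
                         index=["wild", "calm"]), "log2")
        probes = preprocess.select_normalization_probes(m, self.thresholds(["a1", "a2"]))
        assert probes == frozenset({"calm"})
        # boundary: make the SD exactly 1.25 -> excluded under strict <
        x = 1.25 / math.sqrt(2)
        m2 = tables.IntensityMatrix(
            pd.DataFrame({"a1": [8.0 - x, 8.0], "a2": [8.0 + x, 8.1]},
                         index=["edge", "calm"]), "log2")
        probes2 = preprocess.select_normalization_probes(m2, self.thresholds(["a1", "a2"]))
        assert probes2 == frozenset({"calm"})

    def test_constant_probe_above_thresholds_included(self):
        m = tables.IntensityMatrix(
            pd.DataFrame({"a1": [8.0], "a2": [8.0]}, index=["p"]), "log2")
        assert preprocess.select_normalization_probes(
            m, self.thresholds(["a1", "a2"])) == frozenset({"p"})

    def test_empty_qualification_is_error(self):
        m = tables.IntensityMatrix(
            pd.DataFrame({"a1": [4.0], "a2": [4.0]}, index=["p"]), "log2")
        with pytest.raises(QualificationError):
            preprocess.select_normalization_probes(m, self.thresholds(["a1", "a2"]))

    def test_raising_margin_never_adds_probes(self):
        rng = np.random.default_rng(5)
        m = tables.IntensityMatrix(
            pd.DataFrame(rng.uniform(4, 10, (50, 4)),
                         index=[f"p{i}" for i in range(50)],
                         columns=list("abcd")), "log2")
        thr = DetectionThresholds(pd.Series(4.5, index=list("abcd")))
        previous = None
        for margin in (0.5, 1.0, 1.5, 2.0):
            try:
                probes = preprocess.select_normalization_probes(m, thr, margin=margin)
            except QualificationError:
                probes = frozenset()
            if previous is not None:
                assert probes <= previous
            previous = probes


class TestTrimmedMeanAndNormalize:
    @pytest.mark.parametrize("values,trim,expected", [
        (list(range(1, 11)), 0.20, 5.5),
        (list(range(1, 11)), 0.0, 5.5),
        ([3.0, 1.0, 2.0], 0.0, 2.0),
        ([5.0, 5.0, 5.0, 50.0], 0.25, 5.0),
    ])
    def test_trimmed_mean(self, values, trim, expected):
        assert preprocess.compute_normalization_factor(values, trim) == pytest.approx(expected)

    def test_two_array_symmetry(self):
        m = tables.IntensityMatrix(
            pd.DataFrame({"a1": [5.0, 6.0, 7.0], "a2": [6.0, 7.0, 8.0]},
                         index=["p1", "p2", "p3"]), "log2")
        factors = preprocess.normalization_factors(m, frozenset(["p1", "p2", "p3"]))
        assert factors.n.tolist() == [6.0, 7.0]
        assert factors.grand_mean == 6.5
        normalized = preprocess.normalize(m, factors)
        for col in normalized.data:
            assert normalized.data[col].tolist() == [5.5, 6.5, 7.5]

    def test_equal_factors_leave_matrix_unchanged(self):
        m = tables.IntensityMatrix(
            pd.DataFrame({"a1": [5.0, 9.0], "a2": [6.0, 8.0]}, index=["p", "q"]),
            "log2")
        factors = preprocess.NormalizationFactors(
            n=pd.Series({"a1": 7.0, "a2": 7.0}), grand_mean=7.0,
            qualifying_probes=frozenset({"p"}))
        out = preprocess.normalize(m, factors)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_shift_property_preserves_differences(self):
        """+c on one array moves every value by c/K; contrasts survive."""
        rng = np.random.default_rng(11)
        data = pd.DataFrame(rng.uniform(6, 10, (30, 4)),
                            index=[f"p{i}" for i in range(30)],
                            columns=list("abcd"))
        shifted = data.copy()
        c = 0.7
        shifted["b"] = shifted["b"] + c
        probes = frozenset(data.index)

        def run(df):
            m = tables.IntensityMatrix(df, "log2")
            f = preprocess.normalization_factors(m, probes, trim=0.2)
            return preprocess.normalize(m, f).data

        base, moved = run(data), run(shifted)
        k = data.shape[1]
        assert np.allclose(moved.to_numpy(), (base + c / k).to_numpy(), atol=1e-9)

    def test_missing_factor_is_error(self):
        m = tables.IntensityMatrix(
            pd.DataFrame({"a1": [5.0], "a2": [6.0]}, index=["p"]), "log2")
        factors = preprocess.NormalizationFactors(
            n=pd.Series({"a1": 5.0}), grand_mean=5.0, qualifying_probes=frozenset())
        with pytest.raises(ConsistencyError):
            preprocess.normalize(m, factors)


class TestAveragingAndDetection:
    def spots(self, values, flags):
        return pd.DataFrame({
            "array_id": "a1", "probe_id": "p",
            "replicate_index": [1, 2, 3], "value": values, "flag": flags})

    @pytest.mark.parametrize("flags,expected", [
        (["ok", "ok", "ok"], 5.0),
        (["ok", "poor_quality", "ok"], 5.0),
    ])
    def test_triplicate_mean_skips_flagged(self, flags, expected):
        m = preprocess.average_triplicates(self.spots([4.0, 5.0, 6.0], flags))
        assert m.data.loc["p", "a1"] == pytest.approx(expected)

    def test_all_flagged_becomes_missing(self):
        m = preprocess.average_triplicates(
            self.spots([4.0, 5.0, 6.0], ["poor_quality"] * 3))
        assert np.isnan(m.data.loc["p", "a1"])

    def test_boundary_detection_fraction(self):
        arrays = [f"a{i}" for i in range(10)]
        row = [4.0] * 10
        row[0] = 8.0  # detected in exactly 1 of 10 arrays
        m = tables.IntensityMatrix(
            pd.DataFrame([row, [4.0] * 10], index=["kept", "dropped"],
                         columns=arrays), "averaged")
        thr = DetectionThresholds(pd.Series(5.0, index=arrays))
        out = preprocess.detection_filter(m, thr, margin=1.0, min_fraction=0.10)
        assert list(out.data.index) == ["kept"]

    def test_lowering_fraction_never_removes(self):
        rng = np.random.default_rng(3)
        arrays = [f"a{i}" for i in range(10)]
        m = tables.IntensityMatrix(
            pd.DataFrame(rng.uniform(4, 8, (40, 10)),
                         index=[f"p{i}" for i in range(40)], columns=arrays),
            "averaged")
        thr = DetectionThresholds(pd.Series(5.0, index=arrays))
        kept = None
        for frac in (0.9, 0.5, 0.3, 0.1):
            out = set(preprocess.detection_filter(m, thr, min_fraction=frac).data.index)
            if kept is not None:
                assert kept <= out
            kept = out


class TestQcReport:
    def test_zero_noise_experiment_qc(self, small_experiment):
        spots, annotation, design, truth = small_experiment
        thr = preprocess.thresholds_from_spots(spots, annotation)
        slog = preprocess.spot_log2(spots)
        report = preprocess.qc_report(slog, annotation, thr)
        # every spike probe detected on every array
        n_spikes = (annotation["probe_class"] == "spike").sum()
        assert (report.spikes_detected == n_spikes).all()
        # identical triplicates at zero noise -> zero replicate spread
        assert report.replicate_sd["sd"].abs().max() == pytest.approx(0.0)
        # perfect-match probes sit the configured margin above variants
        assert np.allclose(report.specificity_deltas["delta_log2"],
                           truth.config.specificity_delta, atol=1e-9)
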