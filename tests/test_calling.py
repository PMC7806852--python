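import numpy as np
import pytest

from conftest import make_sample
from xmosaic import (
    InputError,
    SampleIntensity,
    check_y_dosage,
    classify_sample,
    estimate_cell_fraction,
    filter_candidate_segments,
)
from xmosaic.segmentation import Segment


def seg(median_lrr, n_probes, span_bp, start=1_000_000):
    s = Segment("s", 0, n_probes)
    s.start_pos = start
    s.end_pos = start + span_bp - 1
    s.median_lrr = median_lrr
    s.mean_lrr = median_lrr
    return s


class TestFilter:
    def test_moderate_gain_retained(self):
        events = filter_candidate_segments([seg(0.20, 300, 5_000_000)])
        assert len(events) == 1
        assert (events[0].direction, events[0].tier) == ("gain", "moderate")

    def test_probe_count_boundary_flips_at_200(self):
        assert not filter_candidate_segments([seg(0.20, 199, 5_000_000)])
        assert filter_candidate_segments([seg(0.20, 200, 5_000_000)])

    def test_lrr_boundary_flips_at_threshold(self):
        assert not filter_candidate_segments([seg(0.1499, 300, 5_000_000)])
        assert filter_candidate_segments([seg(0.15, 300, 5_000_000)])
        assert filter_candidate_segments([seg(-0.15, 300, 5_000_000)])

    def test_span_boundary_flips_at_2mb(self):
        assert not filter_candidate_segments([seg(0.20, 300, 1_999_999)])
        assert filter_candidate_segments([seg(0.20, 300, 2_000_000)])

    def test_high_loss_tagged(self):
        events = filter_candidate_segments([seg(-0.30, 400, 10_000_000)])
        assert (events[0].direction, events[0].tier) == ("loss", "high")

    def test_high_tier_boundary_inclusive(self):
        assert filter_candidate_segments([seg(0.25, 300, 5_000_000)])[0].tier == "high"
        assert filter_candidate_segments([seg(0.2499, 300, 5_000_000)])[0].tier == "moderate"


class TestCellFraction:
    def test_moderate_threshold_maps_to_11_percent(self):
        assert round(100 * estimate_cell_fraction(0.15, "gain")) == 11

    def test_zero_lrr_is_zero_fraction(self):
        assert estimate_cell_fraction(0.0, "gain") == 0.0

    def test_high_threshold_value(self):
        assert estimate_cell_fraction(0.25, "gain") == pytest.approx(0.18921, abs=1e-4)

    def test_loss_formula(self):
        assert estimate_cell_fraction(-0.15, "loss") == pytest.approx(1 - 2**-0.15)

    @pytest.mark.parametrize("direction,sign", [("gain", 1), ("loss", -1)])
    def test_strictly_increasing_in_abs_lrr(self, direction, sign):
        grid = sign * np.linspace(0, 0.9, 50)
        f = [estimate_cell_fraction(v, direction) for v in grid]
        assert np.all(np.diff(f) > 0)

    @pytest.mark.parametrize("f", [0.05, 0.12, 0.2, 0.3, 0.5])
    def test_inverts_generator_model_exactly(self, f):
        assert estimate_cell_fraction(np.log2(1 + f), "gain") == pytest.approx(f)
        assert estimate_cell_fraction(np.log2(1 - f), "loss") == pytest.approx(f)

    def test_wrong_sign_rejected(self):
        with pytest.raises(InputError):
            estimate_cell_fraction(-0.1, "gain")
        with pytest.raises(InputError):
            estimate_cell_fraction(0.1, "loss")


class TestYDosage:
    def _flat(self, probes, y_value):
        lrr = np.zeros(len(probes))
        lrr[probes.is_y] = y_value
        s = SampleIntensity("y", lrr, np.zeros(len(probes)))
        s.corrected = True
        return s

    def test_centred_baseline_is_normal_male(self, probes):
        assert check_y_dosage(self._flat(probes, 0.0), probes) == "NORMAL_MALE"

    def test_deep_negative_is_loss(self, probes):
        assert check_y_dosage(self._flat(probes, -1.2), probes) == "Y_LOSS"

    def test_simulated_y_gain_detected(self, probes):
        from xmosaic import apply_baseline, compute_probe_baseline

        normals = [make_sample(probes, seed=s) for s in range(5)]
        gain = make_sample(probes, seed=9, y_dosage="GAIN")
        base = compute_probe_baseline(normals)
        assert check_y_dosage(apply_baseline(gain, base), probes) == "Y_GAIN"

    def test_no_y_probes_is_unknown(self):
        from xmosaic import build_probe_map

        pm = build_probe_map(100, n_y_probes=0, seed=0)
        s = SampleIntensity("a", np.zeros(100), np.zeros(100))
        with pytest.warns(UserWarning):
            assert check_y_dosage(s, pm) == "UNKNOWN"


class TestClassify:
    def test_xxy_from_whole_chromosome_median(self):
        call = classify_sample("s", 0.55, [], "NORMAL_MALE")
        assert call.call == "CONSTITUTIONAL_XXY"
        assert call.cell_fraction is None

    def test_xxy_boundary_inclusive_at_0p4(self):
        assert classify_sample("s", 0.4, [], "NORMAL_MALE").call == "CONSTITUTIONAL_XXY"
        assert classify_sample("s", 0.3999, [], "NORMAL_MALE").call == "NORMAL"

    def test_moderate_gain_with_fraction(self):
        events = filter_candidate_segments([seg(0.18, 2000, 150_000_000)])
        call = classify_sample("s", 0.18, events, "NORMAL_MALE")
        assert call.call == "MOSAIC_GAIN_MODERATE"
        assert call.cell_fraction == pytest.approx(2**0.18 - 1, abs=1e-6)

    def test_no_events_below_threshold_is_normal(self):
        call = classify_sample("s", 0.01, [], "NORMAL_MALE")
        assert call.call == "NORMAL" and call.cell_fraction is None

    def test_high_tier_takes_priority(self):
        events = filter_candidate_segments(
            [seg(0.18, 2000, 80_000_000), seg(0.30, 500, 10_000_000, start=100_000_000)]
        )
        call = classify_sample("s", 0.2, events, "NORMAL_MALE")
        assert call.call == "MOSAIC_GAIN_HIGH"

    def test_loss_never_coexists_with_xxy(self):
        # a whole-chromosome median >= 0.4 takes the XXY branch before any loss call
        events = filter_candidate_segments([seg(-0.30, 400, 10_000_000)])
        call = classify_sample("s", 0.45, events, "NORMAL_MALE")
        assert call.call == "CONSTITUTIONAL_XXY"
        assert "LOSS" not in call.call
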