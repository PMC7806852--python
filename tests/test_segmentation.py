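import numpy as np
import pytest

from xmosaic import InputError, cbs_segment, segment_stats, smooth_outliers, undo_splits
from xmosaic.experiments import brute_force_best_split
from xmosaic.segmentation import Segment, max_arc_statistic, robust_noise_sd


class TestSmoothing:
    def test_constant_vector_unchanged(self):
        x = np.full(100, 0.3)
        np.testing.assert_array_equal(smooth_outliers(x), x)

    def test_single_spike_shrunk_others_untouched(self):
        x = np.zeros(200)
        x[50] = 10.0
        out = smooth_outliers(x, window=5, clip_sd=3)
        assert out[50] < 10.0
        assert np.all(out[np.arange(200) != 50] == 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.2, 500)
        x[100] += 5.0
        once = smooth_outliers(x)
        np.testing.assert_array_equal(smooth_outliers(once), once)

    def test_short_vector_warned_and_unchanged(self):
        x = np.array([0.0, 1.0, 2.0])
        with pytest.warns(UserWarning):
            out = smooth_outliers(x, window=5)
        np.testing.assert_array_equal(out, x)

    def test_bad_parameters_rejected(self):
        with pytest.raises(InputError):
            smooth_outliers(np.zeros(10), window=4)
        with pytest.raises(InputError):
            smooth_outliers(np.zeros(10), clip_sd=0)


class TestMaxArcStatistic:
    def test_matches_brute_force_on_short_vectors(self):
        """The accepted split equals exhaustive pooled-t maximisation over all arcs."""
        rng = np.random.default_rng(123)
        for _ in range(40):
            n = int(rng.integers(4, 13))
            x = rng.normal(0, 1, n)
            i, j, _ = max_arc_statistic(x)
            assert (i, j) == brute_force_best_split(x)

    def test_clean_step_found_exactly(self):
        x = np.concatenate([np.zeros(30), np.full(20, 1.0)])
        i, j, _ = max_arc_statistic(x)
        assert (i, j) == (0, 30)


class TestCbs:
    def test_noise_free_step_gives_two_segments(self):
        x = np.concatenate([np.zeros(500), np.full(500, 0.3)])
        segs = cbs_segment(x, seed=0)
        assert [(s.start_idx, s.end_idx) for s in segs] == [(0, 500), (500, 1000)]

    def test_noise_free_recovery_on_long_vector(self):
        """Grid+refinement path (n > exhaustive cutoff) still recovers exact breakpoints."""
        x = np.concatenate([np.zeros(1200), np.full(900, 0.4), np.full(900, -0.3)])
        segs = cbs_segment(x, seed=3)
        assert [(s.start_idx, s.end_idx) for s in segs] == [(0, 1200), (1200, 2100), (2100, 3000)]

    def test_pure_noise_rarely_splits(self):
        rng = np.random.default_rng(7)
        n_single = sum(
            len(cbs_segment(rng.normal(0, 0.2, 1000), seed=k)) == 1 for k in range(20)
        )
        assert n_single >= 19

    def test_tiling_invariant_on_noisy_step(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([np.zeros(400), np.full(400, 0.8)]) + rng.normal(0, 0.2, 800)
        segs = cbs_segment(x, seed=5)
        assert segs[0].start_idx == 0 and segs[-1].end_idx == 800
        for a, b in zip(segs, segs[1:]):
            assert b.start_idx == a.end_idx

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(13)
        x = np.concatenate([np.zeros(300), np.full(300, 0.5)]) + rng.normal(0, 0.2, 600)
        a = [(s.start_idx, s.end_idx) for s in cbs_segment(x, seed=9)]
        b = [(s.start_idx, s.end_idx) for s in cbs_segment(x, seed=9)]
        assert a == b

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InputError):
            cbs_segment(np.full(10, np.nan), seed=0)
        with pytest.raises(InputError):
            cbs_segment(np.zeros(10), alpha=1.5, seed=0)
        with pytest.raises(InputError):
            cbs_segment(np.zeros(10), n_perm=50, seed=0)


class TestUndoSplits:
    def _tile(self, bounds):
        return [Segment("s", a, b) for a, b in bounds]

    def test_close_means_merged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.2, 400)
        x[200:] += 0.01
        merged = undo_splits(self._tile([(0, 200), (200, 400)]), x, undo_sd=3)
        assert [(s.start_idx, s.end_idx) for s in merged] == [(0, 400)]

    def test_distant_means_not_merged(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.1, 400)
        x[200:] += 1.0
        kept = undo_splits(self._tile([(0, 200), (200, 400)]), x, undo_sd=3)
        assert len(kept) == 2

    def test_single_segment_passthrough(self):
        x = np.zeros(50)
        out = undo_splits(self._tile([(0, 50)]), x)
        assert [(s.start_idx, s.end_idx) for s in out] == [(0, 50)]

    def test_iterative_merge_is_stable_tiling(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.2, 600)
        out = undo_splits(self._tile([(0, 100), (100, 250), (250, 400), (400, 600)]), x)
        assert out[0].start_idx == 0 and out[-1].end_idx == 600
        for a, b in zip(out, out[1:]):
            assert b.start_idx == a.end_idx

    def test_non_tiling_input_rejected(self):
        with pytest.raises(InputError):
            undo_splits(self._tile([(0, 10), (20, 30)]), np.zeros(30))


class TestSegmentStats:
    def test_direct_computation(self):
        x = np.array([0.1, 0.3, 0.2])
        pos = np.array([100, 200, 300])
        (seg,) = segment_stats([Segment("s", 0, 3)], x, pos)
        assert seg.median_lrr == pytest.approx(0.2)
        assert seg.mean_lrr == pytest.approx(0.2)
        assert seg.n_probes == 3
        assert (seg.start_pos, seg.end_pos) == (100, 300)
        assert seg.span_bp == 201

    def test_recomputation_identical(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 100)
        pos = np.arange(100) * 1000 + 1
        segs = [Segment("s", 0, 40), Segment("s", 40, 100)]
        a = segment_stats(segs, x, pos)
        b = segment_stats(segs, x, pos)
        assert [(s.median_lrr, s.mean_lrr) for s in a] == [(s.median_lrr, s.mean_lrr) for s in b]

    def test_nan_probes_dropped(self):
        x = np.array([0.1, np.nan, 0.3])
        (seg,) = segment_stats([Segment("s", 0, 3)], x, np.array([1, 2, 3]))
        assert seg.median_lrr == pytest.approx(0.2)


def test_robust_noise_sd_estimates_gaussian_sd():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 0.2, 5000)
    assert robust_noise_sd(x) == pytest.approx(0.2, rel=0.1)
    # unaffected by a step: first differences see it only once
    x[2500:] += 2.0
    assert robust_noise_sd(x) == pytest.approx(0.2, rel=0.1)
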