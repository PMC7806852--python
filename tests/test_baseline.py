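import numpy as np
import pytest

from conftest import make_sample
from xmosaic import (
    InputError,
    SampleIntensity,
    apply_baseline,
    compute_probe_baseline,
    median_chrx_lrr,
    qc_filter,
)
from xmosaic.baseline import annotate_qc_stats, chrx_lrr_sd


def _sample(sid, lrr):
    lrr = np.asarray(lrr, dtype=float)
    return SampleIntensity(sid, lrr, np.zeros_like(lrr))


class TestBaseline:
    def test_odd_count_median_per_probe(self):
        samples = [_sample(s, [v]) for s, v in zip("abc", (-0.60, -0.58, -0.55))]
        assert compute_probe_baseline(samples).values[0] == pytest.approx(-0.58)

    def test_even_count_uses_midpoint(self):
        samples = [_sample("a", [-0.6]), _sample("b", [-0.5])]
        assert compute_probe_baseline(samples).values[0] == pytest.approx(-0.55)

    def test_constant_probe_keeps_value(self):
        samples = [_sample(s, [-0.3, 0.1]) for s in "abcd"]
        np.testing.assert_allclose(compute_probe_baseline(samples).values, [-0.3, 0.1])

    def test_nan_values_dropped_probewise(self):
        samples = [_sample("a", [np.nan]), _sample("b", [-0.5]), _sample("c", [-0.4])]
        assert compute_probe_baseline(samples).values[0] == pytest.approx(-0.45)

    def test_single_sample_rejected(self):
        with pytest.raises(InputError):
            compute_probe_baseline([_sample("a", [0.0])])

    def test_misaligned_vectors_rejected(self):
        with pytest.raises(InputError):
            compute_probe_baseline([_sample("a", [0.0]), _sample("b", [0.0, 1.0])])


class TestCorrection:
    def test_subtraction_and_baf_untouched(self):
        samples = [_sample(s, [v]) for s, v in zip("abc", (-0.60, -0.58, -0.55))]
        base = compute_probe_baseline(samples)
        corrected = [apply_baseline(s, base) for s in samples]
        np.testing.assert_allclose(
            [c.lrr[0] for c in corrected], [-0.02, 0.0, 0.03], atol=1e-12
        )
        np.testing.assert_array_equal(corrected[0].baf, samples[0].baf)
        assert corrected[0].corrected and not samples[0].corrected

    def test_zero_baseline_is_identity(self):
        s = _sample("a", [0.1, -0.2])
        base = compute_probe_baseline([_sample("x", [0.0, 0.0]), _sample("y", [0.0, 0.0])])
        np.testing.assert_array_equal(apply_baseline(s, base).lrr, s.lrr)

    def test_corrected_cohort_recentres_to_exact_zero(self, probes):
        """Per-probe cross-sample median of corrected LRR is 0: correction is idempotent."""
        samples = [make_sample(probes, seed=s, noise=0.2) for s in range(7)]
        base = compute_probe_baseline(samples)
        corrected = [apply_baseline(s, base) for s in samples]
        residual = compute_probe_baseline(corrected).values
        assert np.max(np.abs(residual)) == 0.0

    def test_length_mismatch_rejected(self):
        base = compute_probe_baseline([_sample("x", [0.0]), _sample("y", [0.0])])
        with pytest.raises(InputError):
            apply_baseline(_sample("a", [0.1, 0.2]), base)


class TestQc:
    def _with_sd(self, probes, sd, seed=0):
        rng = np.random.default_rng(seed)
        noise = rng.normal(0, 1, probes.n_x)
        if sd > 0:
            noise = (noise - noise.mean()) / noise.std() * sd  # exact population SD on chrX
        else:
            noise = np.zeros(probes.n_x)
        lrr = np.concatenate([noise, np.zeros(probes.n_y)])
        s = SampleIntensity(f"sd{sd}", lrr, np.zeros(len(probes)))
        s.corrected = True
        return s

    def test_boundary_is_inclusive(self, probes):
        kept, excluded = qc_filter(
            [self._with_sd(probes, 0.29), self._with_sd(probes, 0.30), self._with_sd(probes, 0.0)],
            probes,
        )
        assert {s.sample_id for s in kept} == {"sd0.29", "sd0.0"}
        assert [s.sample_id for s, _ in excluded] == ["sd0.3"]
        assert "0.3" in excluded[0][1]

    def test_partition_property(self, probes):
        samples = [make_sample(probes, seed=s) for s in range(5)]
        kept, excluded = qc_filter(samples, probes)
        ids = {s.sample_id for s in kept} | {s.sample_id for s, _ in excluded}
        assert ids == {s.sample_id for s in samples}
        assert not ({s.sample_id for s in kept} & {s.sample_id for s, _ in excluded})

    def test_empty_input_rejected(self, probes):
        with pytest.raises(InputError):
            qc_filter([], probes)

    def test_annotation_fills_stats(self, probes):
        s = make_sample(probes, seed=3)
        annotate_qc_stats(s, probes)
        assert s.lrr_sd is not None and s.median_chrx_lrr is not None
        assert s.lrr_sd == pytest.approx(chrx_lrr_sd(s, probes))


class TestMedianChrX:
    def test_constant_vector(self, probes):
        n = len(probes)
        s = SampleIntensity("a", np.full(n, 0.263), np.zeros(n))
        assert median_chrx_lrr(s, probes) == pytest.approx(0.263)

    def test_noise_free_normal_centres_at_zero(self, probes):
        normals = [make_sample(probes, seed=s, noise=0.0) for s in (1, 2, 3)]
        base = compute_probe_baseline(normals)
        corrected = apply_baseline(normals[0], base)
        assert median_chrx_lrr(corrected, probes) == 0.0

    def test_simple_median(self, probes):
        n = len(probes)
        lrr = np.zeros(n)
        lrr[: probes.n_x] = np.resize([0.1, 0.2, 0.3], probes.n_x)
        s = SampleIntensity("a", lrr, np.zeros(n))
        assert median_chrx_lrr(s, probes) == pytest.approx(0.2)

    def test_xy_normal_cohort_medians_centre_near_zero(self, probes):
        """Sample-median of corrected median chrX LRR within 3 SE of 0."""
        samples = [make_sample(probes, seed=s, noise=0.2) for s in range(9)]
        base = compute_probe_baseline(samples)
        meds = [median_chrx_lrr(apply_baseline(s, base), probes) for s in samples]
        se = 1.2533 * 0.2 / np.sqrt(probes.n_x)  # SE of a sample's probe median
        assert abs(np.median(meds)) <= 3 * se
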