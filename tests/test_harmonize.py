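import numpy as np
import pytest

import wearact as w
from oracles import sorted_median


def _recording(time, acc, labels, rate, subject="S00"):
    return w.Recording(
        time=np.asarray(time, float),
        acc=np.asarray(acc, float),
        labels=np.asarray(labels, object),
        rate=rate,
        subject_id=subject,
    )


def _ramp(rate=50.0, duration=4.0):
    n = int(duration * rate)
    t = np.arange(n) / rate
    acc = np.column_stack([t, 2 * t, -t])
    return _recording(t, acc, ["standing"] * n, rate)


class TestResample:
    def test_same_rate_is_identity(self):
        rec = _ramp(rate=15.0)
        out = w.resample(rec, 15.0)
        assert np.array_equal(out.acc, rec.acc)
        assert np.array_equal(out.time, rec.time)

    def test_linear_signal_interpolates_exactly(self):
        """Linear interpolation reproduces x(t)=t at every 15 Hz time."""
        out = w.resample(_ramp(rate=50.0), 15.0)
        assert np.allclose(out.acc[:, 0], out.time, atol=1e-12)
        assert np.allclose(out.acc[:, 1], 2 * out.time, atol=1e-12)

    def test_sample_count_50hz_to_15hz(self):
        out = w.resample(_ramp(rate=50.0, duration=10.0), 15.0)
        assert abs(len(out) - 150) <= 1
        assert out.rate == 15.0
        assert abs(out.duration - 10.0) <= 1 / 15.0 + 1 / 50.0

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="up-sample"):
            w.resample(_ramp(rate=15.0), 50.0)

    def test_labels_come_from_nearest_sample(self):
        rate = 10.0
        n = 40
        t = np.arange(n) / rate
        labels = ["standing"] * 20 + ["walking"] * 20
        rec = _recording(t, np.zeros((n, 3)), labels, rate)
        out = w.resample(rec, 4.0)
        # nearest original index for each new time
        near = np.array([np.argmin(np.abs(t - tv)) for tv in out.time])
        assert list(out.labels) == [labels[i] for i in near]


class TestRotation:
    def test_identity_is_noop(self):
        rec = _ramp()
        out = w.apply_rotation(rec, np.eye(3))
        assert np.array_equal(out.acc, rec.acc)

    def test_round_trip_through_transpose(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rec = _ramp()
        back = w.apply_rotation(w.apply_rotation(rec, q), q.T)
        assert np.allclose(back.acc, rec.acc, atol=1e-12)

    def test_quarter_turn_about_z(self):
        rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        rec = _recording([0, 0.1], [[1, 0, 0], [1, 0, 0]], ["standing"] * 2, 10.0)
        out = w.apply_rotation(rec, rz)
        assert np.allclose(out.acc, [[0, 1, 0], [0, 1, 0]], atol=1e-12)

    def test_norm_preserved(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rec = _ramp()
        out = w.apply_rotation(rec, q)
        assert np.allclose(
            np.linalg.norm(out.acc, axis=1), np.linalg.norm(rec.acc, axis=1)
        )

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            w.apply_rotation(_ramp(), np.ones((3, 3)))

    def test_axis_permutation_presets(self):
        r = w.rotation_from_axes(("y", "z", "x"))
        # device x points along reference y
        assert np.allclose(r @ np.array([1.0, 0, 0]), [0, 1, 0])
        with pytest.raises(ValueError, match="axis token"):
            w.rotation_from_axes(("x", "y", "w"))


class TestMedianFilter:
    def test_constant_signal_unchanged(self):
        rec = _recording(
            np.arange(10) / 5.0, np.ones((10, 3)), ["standing"] * 10, 5.0
        )
        assert np.array_equal(w.median_filter(rec, 3).acc, rec.acc)

    def test_kernel_one_is_identity(self):
        rec = _ramp()
        assert np.array_equal(w.median_filter(rec, 1).acc, rec.acc)

    def test_spike_removed_by_kernel_three(self):
        acc = np.ones((9, 3))
        acc[4, 1] = 50.0
        rec = _recording(np.arange(9) / 5.0, acc, ["standing"] * 9, 5.0)
        out = w.median_filter(rec, 3)
        # oracle: median of each 3-window by explicit sort
        col = acc[:, 1]
        for i in range(1, 8):
            assert out.acc[i, 1] == sorted_median(col[i - 1 : i + 2])
        assert np.all(out.acc[:, 1] == 1.0)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            w.median_filter(_ramp(), 4)


class TestNormalizeStanding:
    def test_constant_standing_zeroed(self):
        n = 8
        rec = _recording(
            np.arange(n) / 4.0,
            np.tile([0.0, 0.0, 1.0], (n, 1)),
            ["standing"] * n,
            4.0,
        )
        out, ref = w.normalize_standing(rec)
        assert ref.median == (0.0, 0.0, 1.0)
        assert np.array_equal(out.acc, np.zeros((n, 3)))

    def test_post_normalization_standing_median_is_zero(self, rng):
        n = 101
        labels = ["standing"] * 60 + ["supine"] * 41
        rec = _recording(
            np.arange(n) / 10.0, rng.normal(size=(n, 3)), labels, 10.0
        )
        out, _ = w.normalize_standing(rec)
        standing = out.acc[np.asarray(labels, object) == "standing"]
        assert np.allclose(np.median(standing, axis=0), 0.0, atol=1e-12)

    def test_reference_matches_sort_based_median(self, rng):
        n = 33
        rec = _recording(
            np.arange(n) / 10.0, rng.normal(size=(n, 3)), ["standing"] * n, 10.0
        )
        _, ref = w.normalize_standing(rec)
        for k in range(3):
            assert ref.median[k] == pytest.approx(
                sorted_median(rec.acc[:, k]), abs=1e-15
            )

    def test_missing_standing_names_subject(self):
        rec = _recording(
            [0.0, 0.1], np.zeros((2, 3)), ["supine", "supine"], 10.0, subject="S07"
        )
        with pytest.raises(ValueError, match="S07"):
            w.normalize_standing(rec)


class TestFullPipeline:
    def test_identity_config_is_identity_on_normalized_reference(self):
        spec = w.CohortSpec(n_subjects=1, seed=4)
        rec = w.generate_recording(spec, 0)
        normalized, _ = w.normalize_standing(rec)
        cfg = w.HarmonizationConfig(target_rate_hz=15.0, median_kernel=1)
        out, _ = w.harmonize(normalized, cfg)
        assert np.allclose(out.acc, normalized.acc, atol=1e-12)
        assert np.array_equal(out.labels, normalized.labels)

    def test_round_trip_from_rotated_50hz_frame(self):
        """A reference 15 Hz recording re-expressed at 50 Hz in a rotated
        device frame harmonizes back within interpolation tolerance."""
        rot = w.rotation_from_axes(("y", "z", "x"))
        base = dict(
            n_subjects=1, noise_sd=0.0, subject_offset_sd=0.0, seed=2
        )
        ref_rec = w.generate_recording(
            w.CohortSpec(sampling_rate_hz=15.0, **base), 0
        )
        dev_rec = w.generate_recording(
            w.CohortSpec(sampling_rate_hz=50.0, device_rotation=rot, **base), 0
        )
        cfg = w.HarmonizationConfig(
            target_rate_hz=15.0, rotation=rot.T, median_kernel=1
        )
        harmonized, _ = w.harmonize(dev_rec, cfg)
        ref_norm, _ = w.normalize_standing(ref_rec)
        assert len(harmonized) == len(ref_norm)
        assert np.array_equal(harmonized.labels, ref_norm.labels)
        # only the walking sinusoid incurs interpolation error at 50 Hz:
        # |x''|/8 dt^2 = (2 pi f)^2 a / (8 * 50^2) ~ 3e-3 g
        assert np.max(np.abs(harmonized.acc - ref_norm.acc)) < 0.01
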