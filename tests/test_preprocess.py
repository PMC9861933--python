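"""Spectrum I/O and the processing chain."""

import numpy as np
import pytest

from seroprofiler import preprocess as pp
from seroprofiler import synth


def make_spectrum(mz, intensity, **kw):
    return pp.Spectrum(mz=np.asarray(mz, float),
                       intensity=np.asarray(intensity, float), **kw)


def brute_force_opening(values: np.ndarray, size: int) -> np.ndarray:
    """Independent sliding-window erosion/dilation with edge replication."""
    half = size // 2
    padded = np.concatenate([np.full(half, values[0]), values,
                             np.full(half, values[-1])])
    eroded = np.array([padded[i:i + size].min() for i in range(values.size)])
    padded2 = np.concatenate([np.full(half, eroded[0]), eroded,
                              np.full(half, eroded[-1])])
    return np.array([padded2[i:i + size].max() for i in range(values.size)])


class TestIO:
    def test_text_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        s = make_spectrum(np.linspace(1000, 2000, 64), rng.random(64) * 100)
        path = tmp_path / "s.txt"
        pp.write_spectrum(s, path)
        back = pp.read_spectrum(path)
        np.testing.assert_allclose(back.mz, s.mz, rtol=1e-9)
        np.testing.assert_allclose(back.intensity, s.intensity, rtol=1e-9)

    def test_descending_axis_sorted_with_warning(self, tmp_path):
        path = tmp_path / "s.txt"
        mz = np.linspace(2000, 1000, 32)
        lines = "\n".join(f"{m} {i}" for i, m in enumerate(mz))
        path.write_text(lines + "\n")
        with pytest.warns(UserWarning, match="not ascending"):
            s = pp.read_spectrum(path)
        assert (np.diff(s.mz) > 0).all()
        assert s.intensity[0] == 31  # originally last row

    def test_too_few_points_rejected(self, tmp_path):
        path = tmp_path / "s.txt"
        path.write_text("1000 1.0\n")
        with pytest.raises(ValueError, match="minimum"):
            pp.read_spectrum(path)

    def test_non_numeric_rejected(self, tmp_path):
        path = tmp_path / "s.txt"
        path.write_text("1000 a\n1001 2\n")
        with pytest.raises(ValueError):
            pp.read_spectrum(path)


class TestResample:
    def test_identity_on_grid(self):
        mz = np.arange(1000.0, 10001.0)
        s = make_spectrum(mz, np.sin(mz / 100) + 2)
        out = pp.resample([s]).spectra[0]
        np.testing.assert_allclose(out.intensity, s.intensity, rtol=1e-12)

    def test_linear_ramp_exact_at_half_step(self):
        mz = np.arange(1000.0, 2001.0, 2.0)
        s = make_spectrum(mz, 3.0 * mz + 7.0)
        out = pp.resample([s], mz_range=(1000, 2000), step=1.0).spectra[0]
        np.testing.assert_allclose(out.intensity, 3.0 * out.mz + 7.0, rtol=1e-12)

    def test_grid_point_count(self):
        s = make_spectrum(np.linspace(900, 10100, 200), np.ones(200))
        out = pp.resample([s], mz_range=(1000, 10000), step=1.0)
        assert out.axis.size == 9001

    def test_non_overlapping_rejected_by_name(self):
        s = make_spectrum(np.linspace(100, 900, 50), np.ones(50),
                          sample_id="S9")
        with pytest.raises(ValueError, match="S9"):
            pp.resample([s])


class TestSmooth:
    def test_constant_unchanged(self):
        s = make_spectrum(np.arange(1000.0, 1100.0), np.full(100, 4.2))
        out = pp.smooth(s)
        np.testing.assert_allclose(out.intensity, 4.2)

    def test_unit_impulse_quadratic_coefficients(self):
        y = np.zeros(101)
        y[50] = 1.0
        s = make_spectrum(np.arange(1000.0, 1101.0), y)
        out = pp.smooth(s, window_points=5, polyorder=2)
        assert out.intensity[50] == pytest.approx(17 / 35)
        assert out.intensity[49] == pytest.approx(12 / 35)
        assert out.intensity[48] == pytest.approx(-3 / 35)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 1.0, 5000)
        s = make_spectrum(np.arange(5000.0) + 1000, noise + 10)
        out = pp.smooth(s)
        assert out.intensity.std() < noise.std()

    def test_window_larger_than_spectrum_rejected(self):
        s = make_spectrum(np.arange(1000.0, 1016.0), np.ones(16))
        with pytest.raises(ValueError):
            pp.smooth(s, window_points=17)


class TestTophat:
    def test_constant_offset_removed(self):
        s = make_spectrum(np.arange(1000.0, 2000.0), np.full(1000, 5.0))
        out = pp.tophat_baseline(s)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)

    def test_narrow_peak_on_offset_preserved(self):
        mz = np.arange(1000.0, 3001.0)
        peak = 50.0 * np.exp(-0.5 * ((mz - 2000.0) / 8.0) ** 2)
        s = make_spectrum(mz, peak + 7.0)
        out = pp.tophat_baseline(s, min_width_frac=0.10)
        apex = out.intensity[int(np.argmax(out.intensity))]
        assert apex == pytest.approx(50.0, rel=0.01)
        assert out.intensity[0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        mz = np.arange(1000.0, 3001.0)
        y = rng.random(mz.size) * 10 + np.linspace(5, 0, mz.size)
        s = make_spectrum(mz, y)
        size = pp._element_points(s, 0.10)
        expected = y - brute_force_opening(y, size)
        out = pp.tophat_baseline(s, 0.10)
        np.testing.assert_allclose(out.intensity, expected, atol=1e-12)

    def test_opening_idempotent(self):
        rng = np.random.default_rng(3)
        y = rng.random(500) * 4
        once = pp.grey_opening(y, 21)
        twice = pp.grey_opening(once, 21)
        np.testing.assert_allclose(once, twice)

    def test_never_negative(self):
        rng = np.random.default_rng(4)
        mz = np.arange(1000.0, 2001.0)
        s = make_spectrum(mz, rng.random(mz.size) * 3)
        out = pp.tophat_baseline(s)
        assert (out.intensity >= 0).all()


class TestTicNormalize:
    def test_simple_values(self):
        s = make_spectrum([1000, 1001, 1002], [2.0, 3.0, 5.0])
        out = pp.tic_normalize(s)
        np.testing.assert_allclose(out.intensity, [0.2, 0.3, 0.5])
        assert out.intensity.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        y = rng.random(64) + 0.1
        a = pp.tic_normalize(make_spectrum(np.arange(64.0) + 1000, y))
        b = pp.tic_normalize(make_spectrum(np.arange(64.0) + 1000, 37.5 * y))
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)

    def test_zero_spectrum_rejected(self):
        s = make_spectrum(np.arange(32.0) + 1000, np.zeros(32))
        with pytest.raises(ValueError):
            pp.tic_normalize(s)


def _peaky_spectrum(shift=0.0, sample_id="a"):
    mz = np.arange(1000.0, 5001.0)
    y = np.full(mz.size, 1.0)
    for c in (1500.0, 2500.0, 3500.0, 4500.0):
        y += 100.0 * np.exp(-0.5 * ((mz - (c + shift)) / 6.0) ** 2)
    return make_spectrum(mz, y, sample_id=sample_id)


class TestRecalibrate:
    def test_identity_for_identical_spectra(self):
        sset = pp.SpectraSet([_peaky_spectrum(sample_id=f"s{i}")
                              for i in range(4)])
        out = pp.recalibrate(sset)
        for s, o in zip(sset, out):
            np.testing.assert_allclose(o.intensity, s.intensity, atol=1e-9)

    def test_planted_shift_recovered(self):
        spectra = [_peaky_spectrum(sample_id=f"s{i}") for i in range(5)]
        spectra.append(_peaky_spectrum(shift=1.5, sample_id="shifted"))
        out = pp.recalibrate(pp.SpectraSet(spectra))
        corrected = out.spectra[-1]
        apex = corrected.mz[
            np.argmax(corrected.intensity[(corrected.mz > 2400)
                                          & (corrected.mz < 2600)])
            + int(np.flatnonzero(corrected.mz > 2400)[0])
        ]
        assert abs(apex - 2500.0) <= 0.6  # 1.5 Da shift corrected to < grid step

    def test_single_spectrum_skipped_with_warning(self):
        sset = pp.SpectraSet([_peaky_spectrum()])
        with pytest.warns(UserWarning, match="skipped"):
            out = pp.recalibrate(sset)
        np.testing.assert_array_equal(out.spectra[0].intensity,
                                      sset.spectra[0].intensity)

    def test_featureless_spectra_skip_recalibration(self):
        rng = np.random.default_rng(0)
        spectra = [
            make_spectrum(np.arange(1000.0, 1200.0), rng.random(200),
                          sample_id=f"s{i}")
            for i in range(3)
        ]
        with pytest.warns(UserWarning, match="common prominent"):
            pp.recalibrate(pp.SpectraSet(spectra))


class TestGroupingAndMean:
    def _replicates(self, values_by_sample):
        spectra = []
        for sid, arrays in values_by_sample.items():
            for r, vals in enumerate(arrays):
                spectra.append(
                    make_spectrum(np.arange(len(vals), dtype=float) + 1000,
                                  vals, sample_id=sid, replicate=r)
                )
        return pp.SpectraSet(spectra)

    def test_identical_replicates_average_to_same(self):
        vals = np.arange(32.0)
        sset = self._replicates({"a": [vals, vals, vals]})
        out = pp.group_replicates(sset)
        np.testing.assert_allclose(out.spectra[0].intensity, vals)

    def test_pointwise_mean(self):
        sset = self._replicates({"a": [np.zeros(16), np.full(16, 2.0)]})
        out = pp.group_replicates(sset)
        np.testing.assert_allclose(out.spectra[0].intensity, 1.0)

    def test_triplicates_collapse_to_samples(self):
        cfg = synth.SpectrumSimConfig(step=50.0)
        sset = synth.simulate_profiling_dataset(
            cfg, {"allergy": 3, "control": 3}, seed=0
        )
        out = pp.group_replicates(sset)
        assert len(out) == 6
        assert all(s.replicate is None for s in out)

    def test_total_mean_single_is_identity(self):
        s = _peaky_spectrum()
        mean = pp.total_mean_spectrum(pp.SpectraSet([s]))
        np.testing.assert_allclose(mean.intensity, s.intensity)

    def test_total_mean_two_constants(self):
        sset = self._replicates({"a": [np.full(16, 1.0)],
                                 "b": [np.full(16, 3.0)]})
        mean = pp.total_mean_spectrum(sset)
        np.testing.assert_allclose(mean.intensity, 2.0)

    def test_mean_noise_shrinks_as_sqrt_n(self):
        rng = np.random.default_rng(6)
        n, npts = 64, 2000
        spectra = [
            make_spectrum(np.arange(npts, dtype=float) + 1000,
                          rng.normal(0, 1.0, npts) + 10, sample_id=f"s{i}")
            for i in range(n)
        ]
        mean = pp.total_mean_spectrum(pp.SpectraSet(spectra))
        assert mean.intensity.std() == pytest.approx(1.0 / np.sqrt(n), rel=0.25)


class TestPipeline:
    def test_history_records_each_step(self):
        cfg = synth.SpectrumSimConfig(step=10.0)
        sset = synth.simulate_profiling_dataset(
            cfg, {"allergy": 2, "control": 2}, seed=1
        )
        grouped, mean_spec = pp.standard_pipeline(sset, step=10.0)
        history = grouped.spectra[0].history
        joined = " ".join(history)
        for step in ("resample", "recalibrate", "tic_normalize", "smooth",
                     "tophat_baseline", "group_replicates"):
            assert step in joined
        # canonical ordering
        idx = [joined.index(s) for s in
               ("recalibrate", "tic_normalize", "smooth", "tophat_baseline")]
        assert idx == sorted(idx)

    def test_reorder_requires_explicit_override(self):
        cfg = synth.SpectrumSimConfig(step=10.0)
        sset = synth.simulate_profiling_dataset(
            cfg, {"allergy": 2, "control": 2}, seed=1
        )
        order = ("tic_normalize", "smooth", "tophat_baseline", "recalibrate")
        with pytest.raises(ValueError, match="allow_reorder"):
            pp.standard_pipeline(sset, step=10.0, order=order)
        pp.standard_pipeline(sset, step=10.0, order=order, allow_reorder=True)
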