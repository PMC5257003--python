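"""Trace extraction, spectral metrics, normalization, synchrony, epoching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slowosc import (
    ROI,
    StimulusTrain,
    Trace,
    VSDMovie,
    VSDSimParams,
    compute_dff,
    epoch_movie,
    generate_vsd_movie,
    grid_synchrony,
    mean_frequency,
    normalize_powers,
    peak_frequency,
    power_spectrum,
    smooth_trace,
    total_slow_power,
)


def _movie_from(frames):
    return VSDMovie(frames=np.asarray(frames, dtype=float), frame_interval_s=0.05, pixel_size_mm=0.1)


def _sine_trace(freq, amp=1.0, fs=20.0, duration=50.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return Trace(values=amp * np.sin(2 * np.pi * freq * t + phase), sample_interval_s=1 / fs)


class TestComputeDff:
    def test_constant_movie_gives_zero_trace(self):
        movie = _movie_from(np.full((10, 4, 4), 7.0))
        assert np.allclose(compute_dff(movie).values, 0.0)

    def test_two_frame_arithmetic(self):
        movie = _movie_from([np.full((2, 2), 100.0), np.full((2, 2), 110.0)])
        np.testing.assert_allclose(compute_dff(movie).values, [0.0, 10.0])

    def test_baseline_is_lowest_frame_roi_mean(self):
        # frame 1 has the lowest fluorescence; its ROI mean is the baseline
        f0 = np.array([[10.0, 30.0], [10.0, 10.0]])
        f1 = np.array([[5.0, 5.0], [5.0, 5.0]])
        movie = _movie_from([f0, f1])
        roi = ROI(0, 0, 1, 2)  # means 20 and 5
        np.testing.assert_allclose(compute_dff(movie, roi).values, [300.0, 0.0])

    def test_sequence_mean_baseline_option(self):
        movie = _movie_from([np.full((2, 2), 90.0), np.full((2, 2), 110.0)])
        np.testing.assert_allclose(
            compute_dff(movie, baseline="sequence-mean").values, [-10.0, 10.0]
        )

    def test_zero_baseline_rejected(self):
        movie = _movie_from([np.zeros((2, 2)), np.ones((2, 2))])
        with pytest.raises(ValueError, match="F0"):
            compute_dff(movie)

    def test_roi_out_of_bounds_rejected(self):
        movie = _movie_from(np.ones((3, 4, 4)))
        with pytest.raises(ValueError, match="exceeds"):
            compute_dff(movie, ROI(2, 2, 4, 4))

    def test_peak_to_trough_matches_generator_amplitude(self):
        amp = 0.04
        movie, _ = generate_vsd_movie(
            VSDSimParams(osc_amplitude=amp, noise_sd=0.0, waveform="sine", seed=0)
        )
        tr = compute_dff(movie)
        # with the lowest-frame baseline the span is 2a/(1-a), ~2a for small a
        span = tr.values.max() - tr.values.min()
        assert span == pytest.approx(2 * amp * 100, rel=0.05)
        assert span == pytest.approx(2 * amp / (1 - amp) * 100, rel=1e-6)


class TestSmoothTrace:
    def test_order_zero_identity(self):
        tr = Trace(np.arange(10.0), 0.05)
        np.testing.assert_array_equal(smooth_trace(tr, 0).values, tr.values)

    def test_impulse_response_is_binomial_kernel(self):
        x = np.zeros(11)
        x[5] = 1.0
        out = smooth_trace(Trace(x, 0.05), order=2).values
        np.testing.assert_allclose(out[4:7], [0.25, 0.5, 0.25])
        assert np.allclose(out.sum(), 1.0)

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        tr = Trace(rng.normal(size=500), 0.05)
        assert smooth_trace(tr, 4).values.var() < tr.values.var()

    def test_length_preserved(self):
        tr = Trace(np.arange(33.0), 0.05)
        assert smooth_trace(tr, 5).values.size == 33


class TestPowerSpectrum:
    def test_pure_sine_single_dominant_bin(self):
        spec = power_spectrum(_sine_trace(0.6))
        assert spec.df_hz == pytest.approx(0.02)
        assert spec.freqs_hz[np.argmax(spec.psd)] == pytest.approx(0.6)

    def test_constant_trace_all_zero(self):
        spec = power_spectrum(Trace(np.full(100, 3.0), 0.05))
        assert np.allclose(spec.psd, 0.0)

    def test_nonfinite_rejected(self):
        x = np.ones(100)
        x[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            power_spectrum(Trace(x, 0.05))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(64, 1024))
    def test_parseval_identity(self, seed, n):
        """Integrated spectral density equals the trace variance."""
        x = np.random.default_rng(seed).normal(size=n)
        tr = Trace(x, 0.05)
        spec = power_spectrum(tr)
        var = x.var()
        assert np.sum(spec.psd) * spec.df_hz == pytest.approx(var, rel=1e-9)


class TestBandMetrics:
    def test_sine_power_is_half_amplitude_squared(self):
        amp = 0.8
        spec = power_spectrum(_sine_trace(0.6, amp=amp))
        assert total_slow_power(spec) == pytest.approx(amp**2 / 2, rel=1e-6)

    def test_out_of_band_sine_contributes_nothing(self):
        spec = power_spectrum(_sine_trace(1.5))
        assert total_slow_power(spec) == pytest.approx(0.0, abs=1e-12)

    def test_power_scales_quadratically_with_amplitude(self):
        p1 = total_slow_power(power_spectrum(_sine_trace(0.6, amp=1.0)))
        p2 = total_slow_power(power_spectrum(_sine_trace(0.6, amp=0.5)))
        assert p1 / p2 == pytest.approx(4.0, rel=0.01)

    def test_fmax_outside_grid_rejected(self):
        spec = power_spectrum(_sine_trace(0.6))
        with pytest.raises(ValueError):
            total_slow_power(spec, fmax_hz=50.0)

    def test_mean_frequency_of_sine(self):
        spec = power_spectrum(_sine_trace(0.6))
        assert mean_frequency(spec) == pytest.approx(0.6, abs=0.02)

    def test_centroid_of_symmetric_pair(self):
        t = np.arange(1000) / 20.0
        x = np.sin(2 * np.pi * 0.4 * t) + np.sin(2 * np.pi * 0.8 * t)
        spec = power_spectrum(Trace(x, 0.05))
        assert mean_frequency(spec) == pytest.approx(0.6, abs=1e-6)

    def test_zero_band_power_reported_missing(self):
        spec = power_spectrum(_sine_trace(1.5))
        assert np.isnan(mean_frequency(spec, band=(0.0, 1.0)))

    def test_peak_frequency_tracks_dominant_component(self):
        t = np.arange(1000) / 20.0
        x = np.sin(2 * np.pi * 0.4 * t) + 3 * np.sin(2 * np.pi * 0.8 * t)
        assert peak_frequency(power_spectrum(Trace(x, 0.05))) == pytest.approx(0.8)


class TestNormalizePowers:
    def test_reference_mean_exactly_one(self):
        powers = {"wt1": 2.0, "wt2": 4.0, "app1": 0.9}
        out = normalize_powers(powers, reference_ids=["wt1", "wt2"])
        assert out[["wt1", "wt2"]].mean() == pytest.approx(1.0, abs=1e-12)
        assert out["app1"] == pytest.approx(0.3)

    def test_all_equal_powers_normalize_to_one(self):
        out = normalize_powers({"a": 5.0, "b": 5.0, "c": 5.0}, reference_ids=["a", "b"])
        assert np.allclose(out.values, 1.0)

    def test_strata_are_normalized_independently(self):
        powers = {"wt_y": 2.0, "app_y": 1.0, "wt_o": 8.0, "app_o": 2.0}
        strata = {"wt_y": "young", "app_y": "young", "wt_o": "old", "app_o": "old"}
        out = normalize_powers(powers, reference_ids=["wt_y", "wt_o"], strata=strata)
        assert out["app_y"] == pytest.approx(0.5)
        assert out["app_o"] == pytest.approx(0.25)
        assert out["wt_y"] == out["wt_o"] == pytest.approx(1.0)

    def test_empty_or_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_powers({"a": 1.0}, reference_ids=["zz"])
        with pytest.raises(ValueError):
            normalize_powers({"a": 0.0, "b": 1.0}, reference_ids=["a"])


class TestGridSynchrony:
    def test_three_mm_field_yields_nine_tiles(self, clean_vsd_movie):
        movie, _ = clean_vsd_movie
        assert len(grid_synchrony(movie, tile_mm=1.0).tile_traces) == 9

    def test_synchronized_noiseless_index_is_one(self, clean_vsd_movie):
        movie, _ = clean_vsd_movie
        assert grid_synchrony(movie).synchrony_index == pytest.approx(1.0)

    def test_phase_jitter_lowers_index(self):
        sync0 = grid_synchrony(generate_vsd_movie(VSDSimParams(seed=2))[0])
        syncj = grid_synchrony(
            generate_vsd_movie(VSDSimParams(tile_phase_jitter_rad=np.pi, seed=2))[0]
        )
        assert syncj.synchrony_index < sync0.synchrony_index

    def test_zero_variance_tile_reported_missing(self):
        frames = np.ones((100, 20, 20))
        t = np.arange(100) * 0.05
        frames[:, :10, :10] += np.sin(2 * np.pi * 0.6 * t)[:, None, None] * 0.0
        # entire movie constant: every correlation undefined
        movie = VSDMovie(frames=frames + 1.0, frame_interval_s=0.05, pixel_size_mm=0.1)
        sync = grid_synchrony(movie, tile_mm=1.0)
        off = sync.pairwise_corr[~np.eye(4, dtype=bool)]
        assert np.all(np.isnan(off))


class TestEpochMovie:
    @pytest.mark.parametrize(
        "duration, expected",
        [(150.0, 3), (50.0, 1), (170.0, 3)],
    )
    def test_epoch_count_and_remainder_rule(self, duration, expected):
        n = int(duration / 0.05)
        movie = _movie_from(np.random.default_rng(0).normal(size=(n, 2, 2)) + 10)
        epochs = epoch_movie(movie, epoch_s=50.0)
        assert len(epochs) == expected
        assert all(ep.n_frames == 1000 for ep in epochs)

    def test_too_short_movie_rejected(self):
        movie = _movie_from(np.ones((100, 2, 2)))
        with pytest.raises(ValueError, match="epoch"):
            epoch_movie(movie, epoch_s=50.0)


class TestDesynchronizationProperty:
    def test_jitter_reduces_whole_field_power_but_not_tile_power(self):
        """Phase dispersion across tiles cancels in the field average while each
        tile keeps oscillating at full amplitude — the computational analogue of
        desynchronized cortex."""
        jitters = [0.0, 1.0, np.pi]
        field_powers, tile_power_sets = [], []
        for j in jitters:
            movie, truth = generate_vsd_movie(
                VSDSimParams(tile_phase_jitter_rad=j, noise_sd=0.0, seed=7)
            )
            spec = power_spectrum(compute_dff(movie))
            field_powers.append(total_slow_power(spec))
            sync = grid_synchrony(movie)
            tile_power_sets.append(
                [total_slow_power(power_spectrum(t)) for t in sync.tile_traces]
            )
        assert field_powers[0] > field_powers[1] > field_powers[2]
        ref = np.mean(tile_power_sets[0])
        for powers in tile_power_sets:
            assert np.all(np.abs(np.asarray(powers) / ref - 1.0) < 0.05)


class TestEntrainment:
    def test_stimulation_doubles_dominant_frequency_then_reverts(self):
        stim = StimulusTrain(rate_hz=1.2, pulse_width_s=0.4, onset_s=50.0, offset_s=100.0)
        params = VSDSimParams(duration_s=150.0, noise_sd=1.0, seed=11)
        movie, _ = generate_vsd_movie(params, stim)
        peaks = []
        for ep in epoch_movie(movie, epoch_s=50.0):
            peaks.append(peak_frequency(power_spectrum(compute_dff(ep)), band=(0.0, 2.0)))
        pre, during, post = peaks
        assert during == pytest.approx(1.2, abs=0.02)
        assert pre == pytest.approx(0.6, abs=0.02)
        assert post == pytest.approx(0.6, abs=0.02)
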