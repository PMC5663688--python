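import numpy as np
import pytest

from mfakit.coverage import CoverageTrack, WindowScheme
from mfakit.genome import circular_distance
from mfakit.mfa import (MarkerFrequencyTrack, TrackMismatchError, call_origins,
                        fit_gradient_origin, mfa_ratio, smooth_track)


def _track(corrected, label="", W=1000, S=500, L=None):
    corrected = np.asarray(corrected, float)
    n = len(corrected)
    L = L if L is not None else n * S
    return CoverageTrack(
        genome_id="chr", genome_length=L, scheme=WindowScheme(W, S),
        starts=np.arange(n) * S, gc=np.full(n, 0.5), coverage=corrected.copy(),
        corrected=corrected, total_aligned_bases=int(corrected.sum()),
        label=label,
    )


def _mfa_from_values(values, L=None, **kwargs):
    """MarkerFrequencyTrack with prescribed (already-centred) log2 values."""
    values = np.asarray(values, float)
    exp = _track(np.exp2(values) * 1000.0, L=L)
    stat = _track(np.full(len(values), 1000.0), L=L)
    t = mfa_ratio(exp, stat, pseudocount=0.0, **kwargs)
    return t


class TestMfaRatio:
    def test_identical_tracks_give_zero_everywhere(self):
        exp = _track(np.full(40, 800.0))
        stat = _track(np.full(40, 800.0))
        t = mfa_ratio(exp, stat)
        np.testing.assert_allclose(t.log2_ratio, 0.0)
        assert t.median_shift == pytest.approx(0.0)

    def test_doubled_window_is_plus_one(self):
        cov = np.full(41, 1000.0)
        cov[20] = 2000.0
        t = mfa_ratio(_track(cov), _track(np.full(41, 1000.0)))
        # library scaling moves everything slightly; the median re-centring
        # restores the background to ~0 and the doubled window to ~+1
        assert t.log2_ratio[20] == pytest.approx(1.0, abs=0.01)
        assert np.abs(np.delete(t.log2_ratio, 20)).max() < 0.01

    def test_library_size_scaling_removes_depth_offset(self):
        # exponential sequenced 3x deeper: ratios must still centre at 0
        t = mfa_ratio(_track(np.full(40, 3000.0)), _track(np.full(40, 1000.0)))
        np.testing.assert_allclose(t.log2_ratio, 0.0, atol=1e-12)

    def test_zero_stationary_window_masked_not_infinite(self):
        stat = np.full(40, 1000.0)
        stat[7] = 0.0
        t = mfa_ratio(_track(np.full(40, 1000.0)), _track(stat))
        assert t.mask[7]
        assert t.mask_reason[7] == "low_stationary_coverage"
        assert np.isnan(t.log2_ratio[7])
        assert np.isfinite(t.log2_ratio[~t.mask]).all()

    def test_scheme_mismatch_rejected(self):
        a = _track(np.full(40, 1000.0))
        b = CoverageTrack(genome_id="chr", genome_length=40 * 500,
                          scheme=WindowScheme(2000, 500),
                          starts=np.arange(40) * 500,
                          corrected=np.full(40, 1000.0))
        with pytest.raises(TrackMismatchError):
            mfa_ratio(a, b)

    def test_swap_negates_raw_ratios_exactly(self, rng):
        exp = _track(rng.uniform(500, 2000, size=60))
        stat = _track(rng.uniform(500, 2000, size=60))
        fwd = mfa_ratio(exp, stat)
        rev = mfa_ratio(stat, exp)
        ok = ~(fwd.mask | rev.mask)
        assert ok.any()
        # bitwise-exact antisymmetry before re-centring
        np.testing.assert_array_equal(fwd.log2_raw[ok], -rev.log2_raw[ok])

    def test_tsv_round_trip(self, tmp_path, rng):
        t = mfa_ratio(_track(rng.uniform(500, 2000, size=30)),
                      _track(rng.uniform(500, 2000, size=30)))
        smooth_track(t, 3)
        path = tmp_path / "mfa.tsv"
        t.to_tsv(path)
        back = MarkerFrequencyTrack.from_tsv(path)
        np.testing.assert_allclose(back.log2_ratio, t.log2_ratio, atol=1e-9)
        np.testing.assert_allclose(back.smoothed, t.smoothed, atol=1e-9)
        assert back.median_shift == pytest.approx(t.median_shift)


class TestSmoothTrack:
    def test_constant_track_unchanged(self):
        t = _mfa_from_values(np.zeros(30))
        smooth_track(t, 5)
        np.testing.assert_allclose(t.smoothed, 0.0, atol=1e-12)

    def test_single_spike_spreads_to_height_over_span(self):
        v = np.zeros(31)
        v[15] = 1.0
        t = _mfa_from_values(v)
        t.log2_ratio = v  # bypass re-centring for exact convolution arithmetic
        smooth_track(t, 5)
        assert t.smoothed[15] == pytest.approx(1 / 5)
        assert t.smoothed[13] == pytest.approx(1 / 5)
        assert t.smoothed[12] == pytest.approx(0.0)

    def test_circular_spike_wraps_into_last_windows(self):
        v = np.zeros(20)
        v[0] = 1.0
        t = _mfa_from_values(v)
        t.log2_ratio = v
        smooth_track(t, 5)
        assert t.smoothed[19] == pytest.approx(1 / 5)
        assert t.smoothed[18] == pytest.approx(1 / 5)
        assert t.smoothed[17] == pytest.approx(0.0)

    def test_even_span_rejected(self):
        t = _mfa_from_values(np.zeros(10))
        with pytest.raises(ValueError):
            smooth_track(t, 4)

    def test_mask_propagates_when_majority_masked(self):
        v = np.zeros(20)
        t = _mfa_from_values(v)
        t.log2_ratio = v.copy()
        t.log2_ratio[5:8] = np.nan
        smooth_track(t, 5)
        assert np.isnan(t.smoothed[6])      # 3 of 5 masked
        assert np.isfinite(t.smoothed[4])   # 2 of 5 masked: partial mean


class TestCallOrigins:
    def test_flat_track_yields_no_calls(self):
        t = _mfa_from_values(np.zeros(50))
        smooth_track(t, 3)
        assert call_origins(t) == []

    def test_rectangular_peak_called_with_interval(self):
        v = np.zeros(60)
        v[20:30] = 0.5
        t = _mfa_from_values(v)
        t.log2_ratio = v
        smooth_track(t, 1)
        calls = call_origins(t, threshold_log2=0.15, min_width_windows=5)
        assert len(calls) == 1
        c = calls[0]
        assert c.n_windows == 10
        assert c.height == pytest.approx(0.5)
        assert c.interval_start == 20 * 500
        assert 20 * 500 < c.peak < 30 * 500
        assert c.width_bp == 10 * 500

    def test_narrow_peak_filtered_by_min_width(self):
        v = np.zeros(60)
        v[10:13] = 1.0
        t = _mfa_from_values(v)
        t.log2_ratio = v
        smooth_track(t, 1)
        assert call_origins(t, min_width_windows=5) == []

    def test_gap_merging_joins_split_peak(self):
        v = np.zeros(60)
        v[20:26] = 0.5
        v[27:33] = 0.5   # one-window dip inside a single broad peak
        t = _mfa_from_values(v)
        t.log2_ratio = v
        smooth_track(t, 1)
        calls = call_origins(t, merge_gap_windows=3)
        assert len(calls) == 1
        assert calls[0].n_windows == 13

    def test_calls_sorted_by_height_then_position(self):
        v = np.zeros(80)
        v[10:20] = 0.3
        v[40:50] = 0.8
        t = _mfa_from_values(v)
        t.log2_ratio = v
        smooth_track(t, 1)
        calls = call_origins(t)
        assert len(calls) == 2
        assert calls[0].height > calls[1].height
        assert 40 * 500 < calls[0].peak < 50 * 500

    def test_wrap_spanning_peak_is_single_call(self):
        v = np.zeros(60)
        v[:5] = 0.5
        v[-5:] = 0.5
        t = _mfa_from_values(v)
        t.log2_ratio = v
        smooth_track(t, 1)
        calls = call_origins(t)
        assert len(calls) == 1
        assert calls[0].n_windows == 10

    def test_rotation_equivariance(self):
        v = np.zeros(64)
        v[20:30] = np.concatenate([np.linspace(0.2, 0.6, 5),
                                   np.linspace(0.6, 0.2, 5)])
        shift = 16
        t1 = _mfa_from_values(v)
        t1.log2_ratio = v
        smooth_track(t1, 3)
        t2 = _mfa_from_values(np.roll(v, shift))
        t2.log2_ratio = np.roll(v, shift)
        smooth_track(t2, 3)
        c1 = call_origins(t1)
        c2 = call_origins(t2)
        assert len(c1) == len(c2) == 1
        L = t1.genome_length
        assert (c2[0].peak - c1[0].peak) % L == shift * 500


class TestGradientFit:
    def test_noiseless_triangle_recovers_origin_and_amplitude(self):
        L = 500_000
        S, W = 500, 1000
        n = L // S
        mids = (np.arange(n) * S + W // 2) % L
        true_origin = 123_456
        k = 1.0
        d = np.abs(mids - true_origin)
        d = np.minimum(d, L - d)
        values = k * (1 - d / (L / 2))
        t = _mfa_from_values(values - np.median(values), L=L)
        fit = fit_gradient_origin(t)
        assert circular_distance(fit.origin, true_origin, L) <= S
        assert fit.amplitude == pytest.approx(k, rel=0.01)
        assert fit.correlation > 0.999

    def test_flat_track_has_negligible_amplitude(self, rng):
        t = _mfa_from_values(rng.normal(0, 0.05, size=400))
        fit = fit_gradient_origin(t)
        assert abs(fit.amplitude) < 0.05
        assert abs(fit.correlation) < 0.5
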