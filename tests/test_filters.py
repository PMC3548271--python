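"""Filter cascade: band responses, MUA, common reference, SALPA."""

import numpy as np
import pytest

from neuroloop.core import MultiChannelWindow, TimeBase
from neuroloop.filters import (BandSpec, SalpaParams, common_reference,
                               compute_mua, extract_lfp, extract_spike_band,
                               make_filter_state, salpa, SPIKE_BAND, LFP_BAND)
from neuroloop.plant import ArtifactParams, gen_artifact_trace

FS = 25_000.0


def _win(values, fs=FS):
    return MultiChannelWindow(0, np.atleast_2d(np.asarray(values, float)),
                              TimeBase(fs))


def _sine(freq, duration, fs=FS, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _settled_amplitude(x, frac=0.5):
    tail = x[int(len(x) * frac):]
    return (tail.max() - tail.min()) / 2


class TestBandSpec:
    def test_rejects_inverted_band(self):
        with pytest.raises(ValueError):
            BandSpec(500, 100)

    def test_rejects_band_above_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            extract_spike_band(_win(np.zeros(100)), BandSpec(200, 20_000))


class TestSpikeBand:
    def test_dc_rejected(self):
        out = extract_spike_band(_win(np.full(25_000, 3.0)))
        assert np.abs(out.values[0, -1000:]).max() < 3.0 * 1e-2

    def test_inband_1khz_passes(self):
        out = extract_spike_band(_win(_sine(1000, 1.0)))
        assert _settled_amplitude(out.values[0]) == pytest.approx(1.0, rel=0.05)

    def test_below_band_10hz_attenuated(self):
        out = extract_spike_band(_win(_sine(10, 2.0)))
        assert _settled_amplitude(out.values[0]) < 0.1

    def test_linearity_superposition(self):
        a, b = _sine(800, 0.5), _sine(2500, 0.5)
        fa = extract_spike_band(_win(a)).values
        fb = extract_spike_band(_win(b)).values
        fab = extract_spike_band(_win(a + b)).values
        np.testing.assert_allclose(fab, fa + fb, atol=1e-9)

    def test_streaming_state_equals_batch(self):
        """Filtering chunk-by-chunk with carried state equals filtering the
        concatenated signal."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 10_000))
        batch = extract_spike_band(_win(x)).values
        state = make_filter_state(SPIKE_BAND, FS, 3)
        chunks = []
        pos = 0
        for n in (1000, 2500, 123, 6377):
            w = MultiChannelWindow(pos, x[:, pos:pos + n], TimeBase(FS))
            chunks.append(extract_spike_band(w, state=state).values)
            pos += n
        np.testing.assert_allclose(np.concatenate(chunks, axis=1), batch,
                                   atol=1e-12)


class TestLfp:
    def test_decimation_arithmetic(self):
        out = extract_lfp(_win(np.zeros((1, 25_000))), out_rate=2000.0)
        assert out.n_samples == 2000
        assert out.time_base.sample_rate == pytest.approx(2000.0)

    def test_100hz_passes(self):
        out = extract_lfp(_win(_sine(100, 2.0)), out_rate=2000.0)
        assert _settled_amplitude(out.values[0]) == pytest.approx(1.0, rel=0.05)

    def test_5khz_attenuated(self):
        out = extract_lfp(_win(_sine(5000, 2.0)), out_rate=2000.0)
        assert _settled_amplitude(out.values[0]) < 0.05

    def test_out_rate_nyquist_guard(self):
        with pytest.raises(ValueError, match="Nyquist"):
            extract_lfp(_win(np.zeros(1000)), out_rate=900.0)


class TestMua:
    def test_zero_in_zero_out(self):
        out = compute_mua(_win(np.zeros(5000)))
        assert np.all(out.values == 0)

    def test_rectified_sine_settles_to_two_over_pi(self):
        out = compute_mua(_win(_sine(1000, 3.0)), lowpass_hz=20.0)
        settled = out.values[0, -20_000:].mean()
        assert settled == pytest.approx(2 / np.pi, rel=0.02)

    def test_homogeneity(self):
        x = _sine(1000, 1.0)
        one = compute_mua(_win(x)).values
        two = compute_mua(_win(2 * x)).values
        np.testing.assert_allclose(two, 2 * one, atol=1e-12)


class TestCommonReference:
    def test_identical_channels_cancel(self):
        x = np.tile(_sine(60, 0.1), (4, 1))
        out = common_reference(_win(x), mode="mean", scale=1.0)
        assert np.abs(out.values).max() < 1e-12

    def test_median_of_constant_channels(self):
        x = np.array([[1.0], [2.0], [3.0]]) * np.ones((3, 10))
        out = common_reference(_win(x), mode="median", scale=1.0)
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 0.0, 1.0])

    def test_scale_zero_is_identity(self):
        x = np.random.default_rng(1).normal(size=(3, 100))
        out = common_reference(_win(x), scale=0.0)
        np.testing.assert_array_equal(out.values, x)

    def test_shared_mains_reduced_20db(self):
        rng = np.random.default_rng(2)
        mains = _sine(60, 1.0, amp=1.0)
        x = np.stack([mains + 0.1 * rng.normal(size=mains.size)
                      for _ in range(8)])
        out = common_reference(_win(x), mode="mean", scale=1.0)
        freqs = np.fft.rfftfreq(x.shape[1], 1 / FS)
        k = np.argmin(np.abs(freqs - 60))
        before = np.abs(np.fft.rfft(x[0]))[k]
        after = np.abs(np.fft.rfft(out.values[0]))[k]
        assert 20 * np.log10(before / after) > 20

    def test_needs_two_channels(self):
        with pytest.raises(ValueError):
            common_reference(_win(np.zeros(10)))


class TestSalpa:
    def test_no_onsets_is_identity(self):
        x = np.random.default_rng(0).normal(size=(2, 1000)) * 1e-5
        w = _win(x)
        cleaned, mask = salpa(w, [], SalpaParams())
        np.testing.assert_array_equal(cleaned.values, x)
        assert mask.all()

    def test_cubic_segment_removed(self):
        """A post-stimulus segment that is exactly cubic lies in the fit's
        model space and is subtracted to numerical tolerance."""
        n = 2000
        t = np.arange(n) / FS
        p = SalpaParams(blank_len=0, peg_threshold=1.0, rail=1.0)
        x = np.zeros(n)
        x[500:] = 1e-4 * (1 + 5 * t[:1500] - 300 * t[:1500] ** 2
                          + 4000 * t[:1500] ** 3)
        cleaned, mask = salpa(_win(x), [500], p)
        assert np.abs(cleaned.values[0, 500:500 + p.fit_len]).max() < 1e-12
        np.testing.assert_array_equal(cleaned.values[0, :500], x[:500])

    def test_locality_beyond_fit_region(self):
        """Samples beyond blank + fit region after the onset are untouched."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 5000)) * 1e-5
        p = SalpaParams()
        cleaned, _ = salpa(_win(x.copy()), [1000], p)
        end = 1000 + p.fit_len
        np.testing.assert_array_equal(cleaned.values[0, end:], x[0, end:])
        np.testing.assert_array_equal(cleaned.values[0, :1000], x[0, :1000])

    def test_blank_and_peg_masked(self):
        ap = ArtifactParams()
        win, _ = gen_artifact_trace([0.01], [], ap, duration=0.05, seed=0)
        p = SalpaParams()
        cleaned, mask = salpa(win, [250], p)
        assert not mask[0, 250:250 + p.blank_len].any()
        assert np.all(cleaned.values[0, 250:250 + p.blank_len] == 0)

    def test_injected_spike_amplitude_preserved(self):
        """A 3 ms post-stimulus spike survives artifact subtraction with
        amplitude within 20% of the injected value."""
        ap = ArtifactParams()
        amp = 6 * ap.noise_sigma
        stim = [0.02]
        win, gt = gen_artifact_trace(stim, [(0.023, amp)], ap,
                                     duration=0.06, seed=5)
        cleaned, mask = salpa(win, [int(0.02 * FS)], SalpaParams())
        pk = gt[0]["time"]
        recovered = -cleaned.values[0, pk - 2: pk + 3].min()
        assert recovered == pytest.approx(amp, rel=0.20)
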