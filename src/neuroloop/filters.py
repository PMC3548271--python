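"""Time-series filter cascade for multichannel extracellular recordings.

The cascade mirrors standard practice for multielectrode data: a spike band
(~200-5000 Hz) for single-unit activity, an LFP band (~1-500 Hz) decimated to
its own stream rate, multiunit activity (MUA) obtained by rectifying and
low-pass filtering the spike band, common-mode reference subtraction (mean or
median across electrodes), and stimulus-artifact suppression by subtracting a
locally fitted cubic polynomial from post-stimulus trace segments.

All band filters are causal Butterworth IIR filters (order per band edge is
configurable) so that streaming windows can be processed with carried state;
zero-phase filtering is available as an offline option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .core import MultiChannelWindow, TimeBase

__all__ = [
    "BandSpec",
    "SalpaParams",
    "FilterState",
    "extract_spike_band",
    "extract_lfp",
    "compute_mua",
    "common_reference",
    "salpa",
    "SPIKE_BAND",
    "LFP_BAND",
]


@dataclass(frozen=True)
class BandSpec:
    """A band-pass specification: corner frequencies in Hz and filter order."""

    low_hz: float
    high_hz: float
    order: int = 2
    causal: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(f"need 0 < low_hz < high_hz, got {self.low_hz}, {self.high_hz}")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def validate_for(self, sample_rate: float) -> None:
        if self.high_hz >= sample_rate / 2:
            raise ValueError(
                f"high_hz {self.high_hz} at or above Nyquist ({sample_rate / 2} Hz)"
            )


#: Single-unit activity band.
SPIKE_BAND = BandSpec(200.0, 5000.0)
#: Local field potential band.
LFP_BAND = BandSpec(1.0, 500.0)


class FilterState:
    """Carried IIR state so chunked filtering equals filtering the whole signal."""

    def __init__(self, sos: np.ndarray, n_channels: int):
        self.sos = sos
        self.zi = np.zeros((sos.shape[0], n_channels, 2))

    def apply(self, values: np.ndarray) -> np.ndarray:
        out, self.zi = signal.sosfilt(self.sos, values, axis=-1, zi=self.zi)
        return out


def _band_sos(spec: BandSpec, sample_rate: float) -> np.ndarray:
    spec.validate_for(sample_rate)
    return signal.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
        fs=sample_rate, output="sos",
    )


def _apply(sos: np.ndarray, window: MultiChannelWindow,
           state: FilterState | None, causal: bool) -> np.ndarray:
    if not causal:
        return signal.sosfiltfilt(sos, window.values, axis=-1)
    if state is not None:
        if not np.array_equal(state.sos, sos):
            raise ValueError("filter state was built for a different filter")
        return state.apply(window.values)
    return signal.sosfilt(sos, window.values, axis=-1)


def extract_spike_band(raw: MultiChannelWindow, spec: BandSpec = SPIKE_BAND,
                       state: FilterState | None = None) -> MultiChannelWindow:
    """Band-pass ``raw`` into the single-unit activity band."""
    sos = _band_sos(spec, raw.time_base.sample_rate)
    out = _apply(sos, raw, state, spec.causal)
    return MultiChannelWindow(raw.start_sample, out, raw.time_base)


def make_filter_state(spec: BandSpec, sample_rate: float, n_channels: int) -> FilterState:
    return FilterState(_band_sos(spec, sample_rate), n_channels)


def extract_lfp(raw: MultiChannelWindow, spec: BandSpec = LFP_BAND,
                out_rate: float = 2000.0,
                state: FilterState | None = None) -> MultiChannelWindow:
    """Low-band filter then decimate to the LFP stream rate.

    Anti-aliasing is provided by the band filter itself; decimation keeps
    every k-th sample with ``k = round(in_rate / out_rate)``.
    """
    in_rate = raw.time_base.sample_rate
    if out_rate > in_rate:
        raise ValueError("out_rate exceeds input rate")
    if out_rate <= 2 * spec.high_hz:
        raise ValueError(
            f"out_rate {out_rate} violates Nyquist for band high edge {spec.high_hz}"
        )
    sos = _band_sos(spec, in_rate)
    filt = _apply(sos, raw, state, spec.causal)
    # keep every (in_rate/out_rate)-th sample; the ratio need not be integer
    n_out = int(np.floor(raw.n_samples * out_rate / in_rate))
    idx = np.floor(np.arange(n_out) * in_rate / out_rate).astype(np.int64)
    dec = filt[:, idx]
    tb = TimeBase(out_rate, origin=raw.time_base.origin)
    start = int(np.floor(raw.start_sample * out_rate / in_rate))
    return MultiChannelWindow(start, dec, tb)


def compute_mua(spike_band: MultiChannelWindow, lowpass_hz: float = 20.0,
                order: int = 2) -> MultiChannelWindow:
    """Multiunit activity: rectify the spike band, then low-pass filter."""
    rate = spike_band.time_base.sample_rate
    if lowpass_hz >= rate / 2:
        raise ValueError("lowpass_hz at or above Nyquist")
    sos = signal.butter(order, lowpass_hz, btype="low", fs=rate, output="sos")
    out = signal.sosfilt(sos, np.abs(spike_band.values), axis=-1)
    return MultiChannelWindow(spike_band.start_sample, out, spike_band.time_base)


def common_reference(raw: MultiChannelWindow, mode: str = "mean",
                     scale: float = 1.0) -> MultiChannelWindow:
    """Subtract the scaled across-channel mean or median from every channel."""
    if raw.n_channels < 2:
        raise ValueError("common referencing needs >= 2 channels")
    if mode == "mean":
        ref = raw.values.mean(axis=0)
    elif mode == "median":
        ref = np.median(raw.values, axis=0)
    else:
        raise ValueError(f"mode must be 'mean' or 'median', got {mode!r}")
    out = raw.values - scale * ref[None, :]
    return MultiChannelWindow(raw.start_sample, out, raw.time_base)


@dataclass(frozen=True)
class SalpaParams:
    """Stimulus-artifact suppression parameters.

    half_width
        Half-width (samples) of the sliding cubic fit window; the full window
        is ``2 * half_width + 1`` samples.  At 25 kHz the default 37 gives a
        ~3 ms window, short enough to track a millisecond-scale exponential
        artifact tail while leaving sub-millisecond spike waveforms largely
        untouched.
    blank_len
        Samples invalidated (and zeroed) from each pulse onset.
    peg_threshold
        |voltage| at or above this is treated as amplifier saturation
        ("pegged") and masked invalid.
    rail
        Amplifier full-scale voltage; artifacts cannot exceed it.
    fit_len
        Post-onset samples over which the local fit is subtracted; beyond
        this the trace is passed through unchanged.
    """

    half_width: int = 37
    blank_len: int = 50
    peg_threshold: float = 0.95 * 0.3e-3
    rail: float = 0.3e-3
    fit_len: int = 500

    def __post_init__(self) -> None:
        if self.half_width < 2:
            raise ValueError("half_width must be >= 2 (cubic fit needs >= 4 points)")
        if self.blank_len < 0:
            raise ValueError("blank_len must be >= 0")


def salpa(raw: MultiChannelWindow, stim_onsets: Sequence[int],
          params: SalpaParams = SalpaParams()) -> tuple[MultiChannelWindow, np.ndarray]:
    """Suppress stimulus artifacts by local cubic polynomial subtraction.

    For each stimulus onset, a sliding least-squares cubic over
    ``2 * half_width + 1`` samples (Savitzky-Golay smoothing) is fitted to the
    post-stimulus segment starting at the first non-pegged sample, and the
    fitted value is subtracted sample-by-sample.  The fit is two-pass: after
    a first subtraction, samples with large residuals (putative action
    potentials) are replaced by interpolation from their neighbours and the
    cubic is refitted, so spikes riding on the artifact tail do not drag the
    fit and survive subtraction nearly unattenuated.  Samples within
    ``blank_len`` of the onset and pegged samples are zeroed and flagged
    invalid.  Outside stimulus-affected segments the output equals the input.

    Returns ``(cleaned, valid_mask)`` where ``valid_mask`` has the window's
    shape and is False where samples are unrecoverable.
    """
    onsets = np.asarray(stim_onsets, dtype=np.int64)
    if len(onsets) and np.any(np.diff(onsets) < 0):
        raise ValueError("stim_onsets must be sorted")
    vals = raw.values.copy()
    mask = np.ones_like(vals, dtype=bool)
    win = 2 * params.half_width + 1
    n = raw.n_samples
    for onset in onsets:
        i0 = int(onset) - raw.start_sample
        if i0 >= n or i0 + params.fit_len <= 0:
            continue
        seg_end = min(i0 + params.fit_len, n)
        for ch in range(raw.n_channels):
            lo = max(i0, 0)
            pegged = np.abs(raw.values[ch, lo:seg_end]) >= params.peg_threshold
            # fit support starts at first non-pegged sample after onset
            nz = np.flatnonzero(~pegged)
            if len(nz) == 0:
                vals[ch, lo:seg_end] = 0.0
                mask[ch, lo:seg_end] = False
                continue
            fit_start = lo + int(nz[0])
            seg = vals[ch, fit_start:seg_end]
            if len(seg) >= 5:
                w = min(win, len(seg) if len(seg) % 2 == 1 else len(seg) - 1)
                if w >= 5:
                    sm = signal.savgol_filter(seg, w, 3, mode="interp")
                    resid = seg - sm
                    # second pass: exclude spike-like excursions from the fit
                    noise = np.median(np.abs(resid)) / 0.6745
                    spiky = np.abs(resid) > 4 * noise
                    spiky = np.convolve(spiky, np.ones(5, bool), "same") > 0
                    if spiky.any() and not spiky.all():
                        idx = np.arange(len(seg))
                        despiked = seg.copy()
                        despiked[spiky] = np.interp(
                            idx[spiky], idx[~spiky], seg[~spiky])
                        sm = signal.savgol_filter(despiked, w, 3, mode="interp")
                    vals[ch, fit_start:seg_end] = seg - sm
            # blanking and pegging override the fit
            blank_end = min(lo + max(params.blank_len - (lo - i0), 0), seg_end)
            vals[ch, lo:blank_end] = 0.0
            mask[ch, lo:blank_end] = False
            peg_idx = lo + np.flatnonzero(pegged)
            vals[ch, peg_idx] = 0.0
            mask[ch, peg_idx] = False
    return MultiChannelWindow(raw.start_sample, vals, raw.time_base), mask
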