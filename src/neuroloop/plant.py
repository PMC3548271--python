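"""Synthetic neural-culture plant and signal generators.

This module is the test substrate for the whole toolkit.  It provides:

* a stimulatable dissociated-culture model (:class:`CulturePlant`) combining
  spontaneous Poisson firing, compound network bursts, slowly drifting
  excitability (geometric Ornstein-Uhlenbeck), and per-electrode
  voltage-dependent evoked responses confined to a 30 ms post-stimulus
  window;
* a multichannel LFP generator with seizure-like high-line-length epochs;
* a raw-trace generator with rail-clipped exponential stimulus artifacts and
  injected template spikes, with ground truth for scoring artifact-removal
  pipelines.

The plant is phenomenological (point process + sigmoid dose-response), not a
biophysical network: it exists to exercise controllers and detectors under
realistic statistics, not to model neuroscience.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import MultiChannelWindow, SpikeEvent, StimulusCommand, TimeBase

__all__ = [
    "CultureParams",
    "CulturePlant",
    "make_culture",
    "SeizureLfpParams",
    "gen_seizure_lfp",
    "ArtifactParams",
    "gen_artifact_trace",
    "spike_template",
]


@dataclass(frozen=True)
class CultureParams:
    """Synthetic culture parameters.

    baseline_rate is the spontaneous per-unit rate at excitability 1.
    Excitability follows a mean-reverting log-normal drift with time constant
    ``drift_tau`` and stationary log-std ``drift_sigma``, scaling both
    spontaneous and evoked firing; ``excitability_step`` optionally applies a
    multiplicative step (e.g. a synaptic-blocker-like perturbation) at a
    given time.  Evoked responses: for a pulse of amplitude v on electrode k,
    each unit fires with probability
    ``p_max * sigmoid(slope_k * (v - v50_k)) * excitability`` at a latency
    uniform in (0, evoked_window].
    """

    n_units: int = 30
    n_electrodes: int = 59
    baseline_rate: float = 1.0           # Hz per unit
    burst_rate: float = 6.0              # bursts per minute
    burst_size: int = 4                  # max spikes/unit/burst
    burst_spread: float = 0.200          # s, spikes spread within a burst
    drift_tau: float = 120.0             # s
    drift_sigma: float = 0.3             # stationary std of log-excitability
    v50_range: tuple[float, float] = (0.3, 0.6)    # V
    slope_range: tuple[float, float] = (4.0, 8.0)  # 1/V
    p_max: float = 0.6                   # per-unit evoked probability ceiling
    evoked_window: float = 0.030         # s
    excitability_step: tuple[float, float] | None = None  # (time s, multiplier)
    sample_rate: float = 25_000.0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.burst_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.v50_range[0] <= 0:
            raise ValueError("v50 must be positive")


class CulturePlant:
    """Stimulatable point-process culture model (see module docstring)."""

    def __init__(self, params: CultureParams, seed: int):
        self.params = params
        self.sample_rate = params.sample_rate
        self.n_units = params.n_units
        self.rng = np.random.default_rng(seed)
        p = params
        self.home_electrode = (
            self.rng.integers(0, p.n_electrodes, size=p.n_units)
            if p.n_units else np.empty(0, dtype=int))
        self.v50 = self.rng.uniform(*p.v50_range, size=p.n_electrodes)
        self.slope = self.rng.uniform(*p.slope_range, size=p.n_electrodes)
        # stimulation electrodes: first 10 by convention, overridable
        self.stim_electrodes = list(range(min(10, p.n_electrodes)))
        self.t = 0.0
        mu = -p.drift_sigma ** 2 / 2      # E[excitability] = 1
        self._mu = mu
        self._logx = mu + p.drift_sigma * self.rng.standard_normal() \
            if p.drift_sigma > 0 else mu
        self._next_burst = self._draw_burst_gap()
        self._step_applied = False

    def _draw_burst_gap(self) -> float:
        if self.params.burst_rate <= 0:
            return np.inf
        return float(self.rng.exponential(60.0 / self.params.burst_rate))

    @property
    def excitability(self) -> float:
        e = float(np.exp(self._logx))
        st = self.params.excitability_step
        if st is not None and self.t >= st[0]:
            e *= st[1]
        return e

    def _advance_drift(self, dt: float) -> None:
        p = self.params
        if p.drift_sigma <= 0:
            return
        a = np.exp(-dt / p.drift_tau)
        sd = p.drift_sigma * np.sqrt(1 - a * a)
        self._logx = self._mu + (self._logx - self._mu) * a \
            + sd * self.rng.standard_normal()

    def evoked_probability(self, electrode: int, amplitude: float) -> float:
        """Per-unit firing probability for a pulse (before excitability)."""
        p = self.params
        z = self.slope[electrode] * (amplitude - self.v50[electrode])
        return float(p.p_max / (1.0 + np.exp(-z)))

    def step(self, commands: list[StimulusCommand], dt: float) -> list[SpikeEvent]:
        """Advance the plant by ``dt`` seconds, applying the given pulses."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        p = self.params
        fs = self.sample_rate
        t0 = self.t
        exc = self.excitability
        rng = self.rng
        spikes: list[SpikeEvent] = []
        # spontaneous firing: homogeneous Poisson within the step
        if p.n_units and p.baseline_rate > 0:
            lam = p.baseline_rate * exc * p.n_units * dt
            n_sp = rng.poisson(lam)
            if n_sp:
                ts = t0 + rng.uniform(0, dt, size=n_sp)
                us = rng.integers(0, p.n_units, size=n_sp)
                for ti, ui in zip(ts, us):
                    spikes.append(SpikeEvent(
                        time=int(round(ti * fs)),
                        channel=int(self.home_electrode[ui]), unit=int(ui)))
        # compound bursts: all units fire 1..burst_size spikes within 200 ms
        self._next_burst -= dt
        while self._next_burst <= 0 and p.n_units:
            n_per = int(rng.integers(1, p.burst_size + 1))
            for ui in range(p.n_units):
                ts = t0 + rng.uniform(0, p.burst_spread, size=n_per)
                for ti in ts:
                    spikes.append(SpikeEvent(
                        time=int(round(ti * fs)),
                        channel=int(self.home_electrode[ui]), unit=int(ui)))
            self._next_burst += self._draw_burst_gap()
        # evoked responses: sigmoid dose-response, latency in (0, 30 ms]
        for cmd in commands:
            if p.n_units == 0:
                break
            if cmd.amplitude <= 0:
                continue              # a zero-volt pulse is no stimulation
            prob = min(1.0, self.evoked_probability(cmd.channel, cmd.amplitude) * exc)
            if prob <= 0:
                continue
            fired = np.flatnonzero(rng.random(p.n_units) < prob)
            lats = rng.uniform(0, p.evoked_window, size=len(fired))
            for ui, lat in zip(fired, lats):
                spikes.append(SpikeEvent(
                    time=cmd.time + max(1, int(round(lat * fs))),
                    channel=int(self.home_electrode[ui]), unit=int(ui)))
        self._advance_drift(dt)
        self.t = t0 + dt
        spikes.sort(key=lambda s: (s.time, s.channel))
        return spikes


def make_culture(params: CultureParams, seed: int) -> CulturePlant:
    """Build a seeded culture plant (deterministic under the seed)."""
    return CulturePlant(params, seed)


@dataclass(frozen=True)
class SeizureLfpParams:
    """Seizure-like multichannel LFP generator settings.

    Baseline is low-pass filtered Gaussian noise at ``baseline_sigma`` volts
    RMS.  Within each epoch ``(onset_s, duration_s, amplitude_gain,
    dominant_freq_hz)`` the baseline amplitude is multiplied by the gain and
    an oscillation at the dominant frequency is added on the affected
    channels (all channels by default).
    """

    n_channels: int = 16
    sample_rate: float = 2000.0
    baseline_sigma: float = 50e-6
    baseline_bandwidth: float = 100.0     # Hz, low-pass corner of background
    seizure_epochs: tuple = ()
    affected_channels: int | None = None  # None = all

    def __post_init__(self) -> None:
        eps = sorted(self.seizure_epochs)
        for (a, da, *_), (b, *_rest) in zip(eps, eps[1:]):
            if a + da > b:
                raise ValueError("seizure epochs overlap")
        for ep in self.seizure_epochs:
            if ep[2] <= 1:
                raise ValueError("epoch amplitude gain must exceed 1")


def gen_seizure_lfp(params: SeizureLfpParams, duration: float, seed: int
                    ) -> tuple[MultiChannelWindow, list[tuple]]:
    """Generate multichannel LFP with seizure-like epochs.

    Returns the window and the ground-truth epoch list
    ``[(onset_s, duration_s, gain, freq), ...]``.
    """
    for ep in params.seizure_epochs:
        if ep[0] + ep[1] > duration:
            raise ValueError("duration does not cover all epochs")
    rng = np.random.default_rng(seed)
    fs = params.sample_rate
    n = int(round(duration * fs))
    sos = sps.butter(2, params.baseline_bandwidth, btype="low", fs=fs,
                     output="sos")
    noise = sps.sosfilt(sos, rng.standard_normal((params.n_channels, n)),
                        axis=-1)
    noise *= params.baseline_sigma / noise.std(axis=-1, keepdims=True)
    x = noise
    t = np.arange(n) / fs
    n_aff = params.affected_channels or params.n_channels
    for onset, dur, gain, freq in params.seizure_epochs:
        i0, i1 = int(round(onset * fs)), int(round((onset + dur) * fs))
        chans = rng.choice(params.n_channels, size=n_aff, replace=False)
        osc = gain * params.baseline_sigma * np.sin(
            2 * np.pi * freq * t[i0:i1]
            + rng.uniform(0, 2 * np.pi, size=(n_aff, 1)))
        x[chans, i0:i1] = x[chans, i0:i1] * gain + osc
    tb = TimeBase(fs)
    return MultiChannelWindow(0, x, tb), list(params.seizure_epochs)


def spike_template(fs: float = 25_000.0, trough_width: float = 1.0e-4
                   ) -> np.ndarray:
    """Canonical biphasic extracellular spike template, trough normalized to -1."""
    tt = np.arange(-15, 40) / fs
    w = (-np.exp(-(tt / trough_width) ** 2)
         + 0.35 * np.exp(-((tt - 2.2e-4) / (1.8 * trough_width)) ** 2))
    return w / (-w.min())


@dataclass(frozen=True)
class ArtifactParams:
    """Stimulus-artifact trace shape.

    The artifact is an instantaneous jump to ``peak_gain * rail`` decaying
    exponentially with ``decay_tau``, hard-clipped at the amplifier rail, on
    top of a small smooth settling term and Gaussian background noise.
    """

    rail: float = 0.3e-3                  # V, amplifier full scale
    decay_tau: float = 1.0e-3             # s
    peak_gain: float = 3.0                # pre-clip peak in units of rail
    settle_frac: float = 0.05             # slow settling amplitude, x rail
    settle_len: float = 0.020             # s
    noise_sigma: float = 10e-6            # V RMS background


def gen_artifact_trace(stim_times: list[float],
                       spike_times: list[tuple[float, float]],
                       params: ArtifactParams = ArtifactParams(),
                       duration: float = 1.0,
                       sample_rate: float = 25_000.0,
                       seed: int = 0
                       ) -> tuple[MultiChannelWindow, list[dict]]:
    """Single-channel raw trace with stimulus artifacts and injected spikes.

    ``spike_times`` is a list of ``(time_s, amplitude_V)`` with amplitude the
    (negative-going) trough magnitude.  Ground truth lists every injected
    spike with its sample index and a ``recoverable`` flag (False when the
    spike lands in the rail-clipped region).
    """
    fs = sample_rate
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    x = rng.normal(0, params.noise_sigma, size=n)
    t = np.arange(n) / fs
    peg_mask = np.zeros(n, dtype=bool)
    for st in stim_times:
        if not 0 <= st < duration:
            raise ValueError(f"stim time {st} outside trace")
        i0 = int(round(st * fs))
        seg = slice(i0, min(n, i0 + int(round(8 * params.decay_tau * fs))))
        rel = t[seg] - t[i0]
        art = params.peak_gain * params.rail * np.exp(-rel / params.decay_tau)
        # slow settling term: smooth, low-order; removable by a cubic fit
        sl = np.clip(1 - rel / params.settle_len, 0, None)
        art += params.settle_frac * params.rail * sl ** 2
        clipped = np.clip(art, -params.rail, params.rail)
        peg_mask[seg] |= np.abs(art) >= params.rail
        x[seg] += clipped
    tpl = spike_template(fs)
    ground_truth: list[dict] = []
    for st, amp in spike_times:
        if not 0 <= st < duration:
            raise ValueError(f"spike time {st} outside trace")
        pk = int(round(st * fs))
        i0 = pk - 15
        lo, hi = max(i0, 0), min(i0 + len(tpl), n)
        x[lo:hi] += amp * tpl[lo - i0: hi - i0]
        ground_truth.append({
            "time": pk, "amplitude": amp,
            "recoverable": not bool(peg_mask[pk]),
        })
    tb = TimeBase(fs)
    return MultiChannelWindow(0, x[None, :], tb), ground_truth
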