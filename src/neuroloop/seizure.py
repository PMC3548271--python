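"""Line-length seizure detection and responsive stimulation.

The detector tracks, on every LFP channel, the per-sample line-length
increment ``l_k[t] = |x_k[t] - x_k[t - Ts]|`` smoothed by two first-order
exponential averages with short (1 s) and long (60 s) time constants.  A
seizure is declared when the short average exceeds ``ratio`` times the long
average simultaneously on at least ``min_channels`` channels.  During
stimulus application the averages are frozen so artifacts cannot corrupt
them, and re-triggering is suppressed until the freeze window ends.  Upon
detection a responsive stimulation program cycles biphasic pulses through a
randomly chosen electrode subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MultiChannelWindow, StimulusCommand

__all__ = [
    "LineLengthParams",
    "LineLengthState",
    "ResponseProgram",
    "line_length_increment",
    "update_average",
    "detect_seizure",
    "step",
    "run_detector",
    "make_response",
]


@dataclass(frozen=True)
class LineLengthParams:
    """Detector constants.

    Ts is the LFP sampling period (default 500 us).  tau_fast / tau_slow are
    the short and long averaging time constants; detection requires
    ``L_fast > ratio * L_slow`` on at least ``min_channels`` of the
    ``n_channels`` recording channels.
    """

    Ts: float = 500e-6
    tau_fast: float = 1.0
    tau_slow: float = 60.0
    ratio: float = 2.0
    min_channels: int = 4
    n_channels: int = 16

    def __post_init__(self) -> None:
        if not self.tau_fast < self.tau_slow:
            raise ValueError("need tau_fast < tau_slow")
        if self.ratio <= 1:
            raise ValueError("ratio must exceed 1")
        if not 1 <= self.min_channels <= self.n_channels:
            raise ValueError("need 1 <= min_channels <= n_channels")


@dataclass
class LineLengthState:
    """Per-channel running averages and the previous sample."""

    L_fast: np.ndarray | None = None
    L_slow: np.ndarray | None = None
    x_prev: np.ndarray | None = None
    frozen: bool = False
    armed: bool = True

    @property
    def seeded(self) -> bool:
        return self.L_fast is not None


def line_length_increment(x_t: np.ndarray | float,
                          x_prev: np.ndarray | float) -> np.ndarray | float:
    """Per-sample line-length increment ``|x[t] - x[t - Ts]|``."""
    return np.abs(np.asarray(x_t) - np.asarray(x_prev))


def update_average(L: np.ndarray | float, l: np.ndarray | float,
                   Ts: float, tau: float) -> np.ndarray | float:
    """First-order exponential average: ``l + exp(-Ts/tau) * (L - l)``."""
    if tau <= 0 or Ts <= 0:
        raise ValueError("Ts and tau must be positive")
    return l + np.exp(-Ts / tau) * (np.asarray(L) - l)


def detect_seizure(L_fast: np.ndarray, L_slow: np.ndarray,
                   params: LineLengthParams) -> tuple[bool, np.ndarray]:
    """Multichannel detection criterion.

    Detected iff the strict inequality ``L_fast > ratio * L_slow`` holds on
    at least ``min_channels`` channels.  Returns the flag and the satisfying
    channel indices.
    """
    hot = np.flatnonzero(np.asarray(L_fast) > params.ratio * np.asarray(L_slow))
    return len(hot) >= params.min_channels, hot


def step(state: LineLengthState, lfp_sample: np.ndarray,
         params: LineLengthParams) -> tuple[LineLengthState, bool]:
    """Advance the detector by one LFP sample.

    When frozen, ``x_prev`` still tracks the input but the averages stay
    bit-identical and detection is suppressed.  Both averages are seeded to
    the first computed increment so the ratio starts at 1.  Detection is
    edge-triggered: after a detection fires, the detector re-arms only once
    the multichannel criterion has gone false, so an ongoing event is
    reported once.
    """
    x = np.asarray(lfp_sample, dtype=float)
    if x.shape != (params.n_channels,):
        raise ValueError(f"expected {params.n_channels} channels, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite LFP sample")
    if state.x_prev is None:
        state.x_prev = x.copy()
        return state, False
    l = line_length_increment(x, state.x_prev)
    state.x_prev = x.copy()
    if state.frozen:
        return state, False
    if not state.seeded:
        state.L_fast = l.copy()
        state.L_slow = l.copy()
        return state, False
    state.L_fast = update_average(state.L_fast, l, params.Ts, params.tau_fast)
    state.L_slow = update_average(state.L_slow, l, params.Ts, params.tau_slow)
    criterion, _ = detect_seizure(state.L_fast, state.L_slow, params)
    fired = criterion and state.armed
    if fired:
        state.armed = False
    elif not criterion:
        state.armed = True
    return state, fired


@dataclass(frozen=True)
class ResponseProgram:
    """Responsive stimulation program fired on each detection."""

    n_electrodes: int = 10
    aggregate_rate: float = 45.0
    duration: float = 10.0
    amplitude: float = 1.0
    phase_width: float = 400e-6
    shape: str = "biphasic_square"

    def __post_init__(self) -> None:
        if min(self.n_electrodes, self.aggregate_rate, self.duration,
               self.amplitude, self.phase_width) <= 0:
            raise ValueError("all program fields must be positive")


def make_response(available_electrodes: list[int], program: ResponseProgram,
                  rng_seed: int, start_time: int = 0,
                  sample_rate: float = 2000.0) -> list[StimulusCommand]:
    """Build the detection-triggered stimulation command list.

    ``n_electrodes`` electrodes are sampled without replacement; commands are
    placed at the aggregate period, cycling sequentially through the chosen
    electrodes for the full duration.
    """
    if len(available_electrodes) < program.n_electrodes:
        raise ValueError(
            f"need {program.n_electrodes} electrodes, only "
            f"{len(available_electrodes)} available")
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(available_electrodes, size=program.n_electrodes,
                        replace=False)
    period = 1.0 / program.aggregate_rate
    n_cmds = int(round(program.duration * program.aggregate_rate))
    return [StimulusCommand(
        time=start_time + int(round(i * period * sample_rate)),
        channel=int(chosen[i % program.n_electrodes]),
        amplitude=program.amplitude, phase_width=program.phase_width,
        shape=program.shape)
        for i in range(n_cmds)]


@dataclass
class DetectionRecord:
    time: int                     # sample index of detection
    channels: np.ndarray          # triggering channel set
    commands: list[StimulusCommand] = field(default_factory=list)


def _ll_filter(l: np.ndarray, beta: float, L0: np.ndarray) -> np.ndarray:
    """Vectorized exponential averaging of increments along axis -1."""
    from scipy.signal import lfilter
    zi = (L0 * beta)[:, None]
    out, _ = lfilter([1 - beta], [1, -beta], l, axis=-1, zi=zi)
    return out


def run_detector(lfp: MultiChannelWindow, params: LineLengthParams,
                 program: ResponseProgram | None = None,
                 available_electrodes: list[int] | None = None,
                 post_guard: float = 1.0, warmup: float | None = None,
                 seed: int = 0) -> list[DetectionRecord]:
    """Run detection (and optional responsive stimulation) over a recording.

    Functionally equivalent to calling :func:`step` sample-by-sample, but
    the exponential averages are evaluated with vectorized IIR filtering
    between detections so long recordings run quickly.  On each detection a
    response program is emitted (if given), the averages freeze for the
    program duration plus ``post_guard`` seconds, and detection stays
    suppressed until the freeze ends.  Detections are also suppressed during
    an initial warm-up (default ``tau_slow`` seconds) while the long average
    converges.
    """
    x = lfp.values
    fs = lfp.time_base.sample_rate
    Ts = 1.0 / fs
    if warmup is None:
        warmup = params.tau_slow
    warmup_n = int(round(warmup * fs))
    l = np.abs(np.diff(x, axis=-1))         # increments at samples 1..n-1
    if l.shape[-1] == 0:
        return []
    bf = float(np.exp(-Ts / params.tau_fast))
    bs = float(np.exp(-Ts / params.tau_slow))
    L0 = l[:, 0].copy()
    records: list[DetectionRecord] = []
    pos = 1                                  # increment index seeding L0
    Lf_prev, Ls_prev = L0.copy(), L0.copy()
    if program is not None:
        freeze_n = int(round((program.duration + post_guard) * fs))
    else:
        freeze_n = int(round(post_guard * fs))
    n_inc = l.shape[-1]
    armed = True
    while pos < n_inc:
        Lf = _ll_filter(l[:, pos:], bf, Lf_prev)
        Ls = _ll_filter(l[:, pos:], bs, Ls_prev)
        crit = (Lf > params.ratio * Ls).sum(axis=0) >= params.min_channels
        scan = 0
        fired = False
        n_chunk = len(crit)
        while scan < n_chunk:
            if not armed:
                quiet = np.flatnonzero(~crit[scan:])
                if quiet.size == 0:
                    scan = n_chunk           # criterion never releases
                    break
                scan += int(quiet[0]) + 1
                armed = True
                continue
            hot = np.flatnonzero(crit[scan:])
            if hot.size == 0:
                scan = n_chunk
                break
            rel = scan + int(hot[0])
            det_inc = pos + rel              # increment index of detection
            det_sample = lfp.start_sample + det_inc + 1
            if det_sample < warmup_n:
                # warm-up: the transition is consumed without firing
                armed = False
                scan = rel + 1
                continue
            chans = np.flatnonzero(Lf[:, rel] > params.ratio * Ls[:, rel])
            rec = DetectionRecord(time=det_sample, channels=chans)
            if program is not None and available_electrodes is not None:
                rec.commands = make_response(
                    available_electrodes, program, rng_seed=seed + len(records),
                    start_time=det_sample, sample_rate=fs)
            records.append(rec)
            # freeze: averages held at the detection values through the freeze
            Lf_prev = Lf[:, rel].copy()
            Ls_prev = Ls[:, rel].copy()
            pos = det_inc + freeze_n
            armed = False
            fired = True
            break
        if not fired:
            break
    return records
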