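"""Multichannel population firing-rate clamp.

The controller adjusts the amplitudes of voltage-controlled biphasic pulses
delivered on a small set of stimulation electrodes so that the average
per-unit firing rate of the network tracks a setpoint ``f*``.  Each loop
period ``dT`` the per-electrode voltage is updated multiplicatively:

    v_k <- v_k - alpha * v_k * (f_avg / f* - 1)

which leaves v unchanged at the setpoint, decreases it when the network fires
too fast, and increases it when the network fires too slowly.  The closed
loop behaves like a first-order system with feedback time constant
``tau_FB = dT / alpha``.

Per-electrode tuning factors, inversely proportional to each electrode's
evoked spike count in a 30 ms post-stimulus window, equalize electrode
efficacy.  Stimuli are delivered in a random repeating sequence across
electrodes at a fixed aggregate rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SpikeEvent, StimulusCommand

__all__ = [
    "ClampParams",
    "ClampState",
    "ClampTrajectory",
    "update_voltage",
    "feedback_time_constant",
    "estimate_population_rate",
    "compute_tuning_factors",
    "schedule_stimuli",
    "generate_poisson_protocol",
    "compute_pairwise_correlations",
    "run_clamp",
]


@dataclass(frozen=True)
class ClampParams:
    """Clamp controller parameters.

    alpha
        Unitless feedback gain (0 < alpha < 1).
    dT
        Loop period in seconds (1-150 ms).
    f_star
        Target firing rate, Hz per sorted unit.
    rate_window
        Rectangular window (seconds) over which the population rate is
        averaged.
    tuning_window
        Post-stimulus window (seconds) in which evoked spikes are counted
        for tuning factors.
    tuning_update
        Cadence (seconds) at which tuning factors are recomputed from the
        rolling evoked-spike counts.
    """

    alpha: float = 0.002
    dT: float = 0.010
    f_star: float = 3.0
    rate_window: float = 2.0
    n_stim_electrodes: int = 10
    per_electrode_rate: float = 1.0
    v_init: float = 0.5
    v_max: float = 1.0
    tuning_window: float = 0.030
    tuning_update: float = 60.0
    phase_width: float = 400e-6

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")
        if not 0.001 <= self.dT <= 0.150:
            raise ValueError("dT must lie in [1 ms, 150 ms]")
        if self.f_star <= 0:
            raise ValueError("f_star must be positive")
        if self.v_init > self.v_max:
            raise ValueError("v_init must not exceed v_max")


@dataclass
class ClampState:
    """Mutable controller state during a run."""

    v: np.ndarray                 # per-electrode voltages
    tuning: np.ndarray            # per-electrode unitless factors
    frozen: bool = False          # open-loop mode: voltage updates bypassed
    f_avg: float = 0.0
    t: int = 0                    # current sample


def update_voltage(v_k: float | np.ndarray, f_avg: float,
                   params: ClampParams) -> float | np.ndarray:
    """One multiplicative control update of the electrode voltage(s).

    Returns ``v_k - alpha * v_k * (f_avg / f_star - 1)`` clipped into
    ``[0, v_max]``.
    """
    if params.f_star <= 0:
        raise ValueError("f_star must be positive")
    if np.any(np.asarray(v_k) < 0) or f_avg < 0:
        raise ValueError("v_k and f_avg must be nonnegative")
    out = v_k - params.alpha * v_k * (f_avg / params.f_star - 1.0)
    return np.clip(out, 0.0, params.v_max)


def feedback_time_constant(dT: float, alpha: float) -> float:
    """Closed-loop time constant ``tau_FB = dT / alpha`` in seconds."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return dT / alpha


def estimate_population_rate(spikes: list[SpikeEvent] | np.ndarray, now: int,
                             window: float, n_units: int,
                             sample_rate: float = 25_000.0) -> float:
    """Average per-unit firing rate over the trailing window.

    Counts spikes with time in ``(now - window, now]`` and divides by
    ``window * n_units``.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if window <= 0:
        raise ValueError("window must be positive")
    if isinstance(spikes, np.ndarray):
        times = spikes
    elif len(spikes) and isinstance(spikes[0], SpikeEvent):
        times = np.asarray([s.time for s in spikes])
    else:
        times = np.asarray(spikes)
    lo = now - window * sample_rate
    count = int(np.count_nonzero((times > lo) & (times <= now))) if times.size else 0
    return count / (window * n_units)


def compute_tuning_factors(post_stim_counts: np.ndarray,
                           window: float = 0.030) -> np.ndarray:
    """Per-electrode tuning factors from evoked spike counts.

    Factors are proportional to ``1 / (1 + count)`` (the +1 regularizes the
    zero-count case) and normalized to mean 1 so the average drive is
    unchanged.
    """
    counts = np.asarray(post_stim_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    raw = 1.0 / (1.0 + counts)
    return raw / raw.mean()


def schedule_stimuli(electrodes: list[int], per_electrode_rate: float,
                     duration: float, rng_seed: int,
                     sample_rate: float = 25_000.0,
                     amplitude: float = 0.0,
                     phase_width: float = 400e-6) -> list[StimulusCommand]:
    """Random repeating stimulation schedule.

    Commands are placed on a uniform time grid with period
    ``1 / (n * per_electrode_rate)``; one random permutation of the electrode
    list is drawn once and repeated block after block, so each electrode
    fires exactly once per block.
    """
    if per_electrode_rate <= 0:
        raise ValueError("per_electrode_rate must be positive")
    if not electrodes:
        raise ValueError("electrodes must be non-empty")
    n = len(electrodes)
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    period = 1.0 / (n * per_electrode_rate)
    n_cmds = int(round(duration * n * per_electrode_rate))
    cmds = []
    for i in range(n_cmds):
        t = i * period
        ch = electrodes[perm[i % n]]
        cmds.append(StimulusCommand(
            time=int(round(t * sample_rate)), channel=ch,
            amplitude=amplitude, phase_width=phase_width))
    return cmds


def generate_poisson_protocol(rate: float, trial_len: float, n_trials: int,
                              mode: str = "fresh", amplitude: float = 0.75,
                              phase_width: float = 400e-6, rng_seed: int = 0,
                              sample_rate: float = 25_000.0,
                              channel: int = 0) -> list[list[StimulusCommand]]:
    """Per-trial Poisson stimulus sequences.

    ``fresh`` draws an independent homogeneous Poisson realization per trial;
    ``repeated`` draws one and replicates it across trials.  Command times
    are snapped to the sample grid within each trial.
    """
    if rate <= 0 or n_trials < 1:
        raise ValueError("need rate > 0 and n_trials >= 1")
    if mode not in ("fresh", "repeated"):
        raise ValueError(f"mode must be 'fresh' or 'repeated', got {mode!r}")
    rng = np.random.default_rng(rng_seed)

    def one_trial() -> list[StimulusCommand]:
        times = []
        t = rng.exponential(1.0 / rate)
        while t < trial_len:
            times.append(t)
            t += rng.exponential(1.0 / rate)
        return [StimulusCommand(time=int(round(t * sample_rate)),
                                channel=channel, amplitude=amplitude,
                                phase_width=phase_width)
                for t in times]

    if mode == "repeated":
        trial = one_trial()
        return [list(trial) for _ in range(n_trials)]
    return [one_trial() for _ in range(n_trials)]


def compute_pairwise_correlations(spike_trains: list[np.ndarray], bin: float,
                                  max_lag: float,
                                  duration: float | None = None
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Average pairwise cross-correlation of binned unit firing rates.

    Each train is a 1-D array of spike times in seconds.  Trains are binned
    at ``bin`` seconds; for every unordered pair the normalized (Pearson)
    cross-correlation is evaluated at integer-bin lags up to ``max_lag`` and
    the functions are averaged across pairs.  Pairs in which either train has
    zero variance are skipped with a warning.

    Returns ``(lags_seconds, mean_correlation)``.
    """
    import warnings
    if len(spike_trains) < 2:
        raise ValueError("need >= 2 units")
    if bin <= 0:
        raise ValueError("bin must be positive")
    if duration is None:
        duration = max((t.max() if len(t) else 0.0) for t in spike_trains) + bin
    n_bins = int(np.ceil(duration / bin))
    edges = np.arange(n_bins + 1) * bin
    rates = np.stack([np.histogram(t, bins=edges)[0] for t in spike_trains]).astype(float)
    max_lag_bins = int(round(max_lag / bin))
    lags = np.arange(-max_lag_bins, max_lag_bins + 1)
    acc = np.zeros(len(lags))
    n_pairs = 0
    for i in range(len(rates)):
        for j in range(i + 1, len(rates)):
            a, b = rates[i], rates[j]
            if a.std() == 0 or b.std() == 0:
                warnings.warn(f"unit pair ({i},{j}) has zero-variance rate; skipped")
                continue
            az = (a - a.mean()) / a.std()
            bz = (b - b.mean()) / b.std()
            for li, lag in enumerate(lags):
                if lag >= 0:
                    x, y = az[: len(az) - lag], bz[lag:]
                else:
                    x, y = az[-lag:], bz[: len(bz) + lag]
                acc[li] += float(np.mean(x * y))
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no unit pair had nonzero rate variance")
    return lags * bin, acc / n_pairs


@dataclass
class ClampTrajectory:
    """Recorded closed-loop run: sampled every loop period."""

    t: np.ndarray                 # seconds at each loop step
    f_avg: np.ndarray             # per-unit rate estimate, Hz
    mean_v: np.ndarray            # mean electrode voltage, V
    v: np.ndarray                 # (n_steps, n_electrodes) voltages
    spike_counts: np.ndarray      # population spikes per loop step
    commands: list[StimulusCommand] = field(default_factory=list)
    spikes: list[SpikeEvent] = field(default_factory=list)
    aborted: bool = False
    diagnostic: str = ""


def run_clamp(plant, params: ClampParams, duration: float,
              open_loop_after: float | None = None, seed: int = 0,
              record_spikes: bool = False) -> ClampTrajectory:
    """Run the closed-loop firing-rate clamp against a plant.

    The plant must expose ``n_units``, ``stim_electrodes``, ``sample_rate``
    and a method ``step(commands, dt) -> list[SpikeEvent]`` advancing its
    internal clock by ``dt`` seconds.  Every loop period the controller
    recomputes the population rate over the trailing ``rate_window``, applies
    the voltage update (unless frozen), scales each electrode's amplitude by
    its tuning factor, and emits the scheduled commands falling in that
    period.  At ``open_loop_after`` seconds voltages freeze but stimulation
    continues (open-loop mode).
    """
    fs = plant.sample_rate
    electrodes = list(plant.stim_electrodes)[: params.n_stim_electrodes]
    n_el = len(electrodes)
    el_index = {ch: k for k, ch in enumerate(electrodes)}
    schedule = schedule_stimuli(
        electrodes, params.per_electrode_rate, duration, rng_seed=seed,
        sample_rate=fs, phase_width=params.phase_width)
    n_steps = int(round(duration / params.dT))
    dT_samp = params.dT * fs
    state = ClampState(
        v=np.full(n_el, params.v_init),
        tuning=np.ones(n_el),
    )
    win_steps = max(1, int(round(params.rate_window / params.dT)))
    recent_counts = np.zeros(win_steps)
    # rolling evoked-spike counts for tuning factors
    evoked_counts = np.zeros(n_el)
    last_tuning_update = 0.0
    tuning_window_samp = params.tuning_window * fs
    recent_cmds: list[StimulusCommand] = []

    traj_t = np.empty(n_steps)
    traj_f = np.empty(n_steps)
    traj_mv = np.empty(n_steps)
    traj_v = np.empty((n_steps, n_el))
    traj_counts = np.empty(n_steps)
    all_cmds: list[StimulusCommand] = []
    all_spikes: list[SpikeEvent] = []
    sched_pos = 0
    try:
        for step in range(n_steps):
            t0 = step * params.dT
            now_samp = int(round((step + 1) * dT_samp))
            if open_loop_after is not None and t0 >= open_loop_after:
                state.frozen = True
            # emit scheduled commands due this period, scaled by v * tuning
            cmds = []
            step_lo, step_hi = int(round(step * dT_samp)), now_samp
            while sched_pos < len(schedule) and schedule[sched_pos].time < step_hi:
                c = schedule[sched_pos]
                k = el_index[c.channel]
                amp = float(np.clip(state.v[k] * state.tuning[k], 0.0, params.v_max))
                cmds.append(StimulusCommand(time=c.time, channel=c.channel,
                                            amplitude=amp,
                                            phase_width=c.phase_width))
                sched_pos += 1
            spikes = plant.step(cmds, params.dT)
            all_cmds.extend(cmds)
            if record_spikes:
                all_spikes.extend(spikes)
            # population rate over the trailing rectangular window
            recent_counts[step % win_steps] = len(spikes)
            filled = min(step + 1, win_steps)
            eff_window = filled * params.dT
            total = recent_counts.sum() if step + 1 >= win_steps \
                else recent_counts[:filled].sum()
            state.f_avg = total / (eff_window * plant.n_units)
            # evoked counts for tuning factors
            if cmds:
                spike_times = np.asarray([s.time for s in spikes])
                for c in cmds:
                    k = el_index[c.channel]
                    if spike_times.size:
                        evoked_counts[k] += np.count_nonzero(
                            (spike_times >= c.time)
                            & (spike_times <= c.time + tuning_window_samp))
            recent_cmds = cmds
            if t0 - last_tuning_update >= params.tuning_update and evoked_counts.sum() > 0:
                state.tuning = compute_tuning_factors(evoked_counts)
                evoked_counts[:] = 0.0
                last_tuning_update = t0
            if not state.frozen:
                state.v = update_voltage(state.v, state.f_avg, params)
            state.t = now_samp
            traj_t[step] = t0 + params.dT
            traj_f[step] = state.f_avg
            traj_mv[step] = state.v.mean()
            traj_v[step] = state.v
            traj_counts[step] = len(spikes)
    except Exception as exc:  # plant fault: return partial trajectory
        return ClampTrajectory(
            t=traj_t[:step], f_avg=traj_f[:step], mean_v=traj_mv[:step],
            v=traj_v[:step], spike_counts=traj_counts[:step],
            commands=all_cmds, spikes=all_spikes, aborted=True,
            diagnostic=f"plant fault at t={step * params.dT:.3f}s: {exc}")
    return ClampTrajectory(t=traj_t, f_avg=traj_f, mean_v=traj_mv, v=traj_v,
                           spike_counts=traj_counts, commands=all_cmds,
                           spikes=all_spikes)
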