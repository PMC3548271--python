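"""Discrete-time closed-loop executors with latency accounting.

Two output pathways are modeled:

* **buffered** — double-buffered, block-committed output: the control code
  runs at buffer-swap instants (multiples of the loop period ``dT``), and a
  decision made at one swap can only take physical effect at the *next* swap
  (commit-at-swap semantics).  A trigger landing exactly on a swap instant
  therefore incurs latency ``dT``; any later trigger in the period waits for
  the following swap, giving latencies in ``(dT, 2*dT]``.

* **event_driven** — each incoming data block triggers immediate output
  after an optional per-event ``processing_delay``; latency is the residual
  of the block period plus the delay.

Everything runs in simulated time: identical seeds and configurations give
bit-identical run logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LoopConfig", "LatencyRecord", "run", "latency_stats"]


@dataclass(frozen=True)
class LoopConfig:
    dT: float = 0.010
    mode: str = "buffered"
    processing_delay: float = 0.0
    samples_per_block: int = 1
    sample_rate: float = 25_000.0

    def __post_init__(self) -> None:
        if not 0.001 <= self.dT <= 0.150:
            raise ValueError("dT must lie in [1 ms, 150 ms]")
        if self.mode not in ("buffered", "event_driven"):
            raise ValueError(f"mode must be buffered or event_driven, got {self.mode!r}")
        if self.processing_delay < 0 or self.samples_per_block < 1:
            raise ValueError("bad processing_delay or samples_per_block")


@dataclass(frozen=True)
class LatencyRecord:
    trigger_time: int       # sample index of the triggering event
    output_time: int        # sample index at which output appears
    latency: float          # seconds

    def __post_init__(self) -> None:
        if self.output_time < self.trigger_time:
            raise ValueError("output cannot precede its trigger")


@dataclass
class RunLog:
    records: list[LatencyRecord] = field(default_factory=list)
    outputs: list = field(default_factory=list)
    aborted: bool = False
    diagnostic: str = ""


def _buffered_output_sample(trigger: int, dT_samp: int) -> int:
    """Commit-at-swap: decisions at swap k play out at swap k+1."""
    k = trigger // dT_samp
    if trigger % dT_samp == 0:
        return trigger + dT_samp            # seen at its own swap
    return (k + 2) * dT_samp                # seen at next swap, plays at the one after


def run(plant, processors, controller, cfg: LoopConfig, duration: float,
        seed: int = 0) -> RunLog:
    """Execute a closed loop over trigger events produced by the plant.

    ``plant`` is either a callable ``plant(duration, seed) -> trigger sample
    indices`` or an iterable of trigger sample indices.  ``processors`` is a
    sequence of callables applied to the trigger list in order (e.g. spike
    validation); ``controller`` maps a trigger to an output object (or None
    to ignore it).  Latency is accounted per the configured pathway.
    """
    fs = cfg.sample_rate
    n_total = int(round(duration * fs))
    triggers = plant(duration, seed) if callable(plant) else plant
    triggers = np.asarray(sorted(int(t) for t in triggers))
    triggers = triggers[(triggers >= 0) & (triggers < n_total)]
    for proc in processors or ():
        triggers = np.asarray(proc(triggers))
    dT_samp = int(round(cfg.dT * fs))
    delay_samp = int(round(cfg.processing_delay * fs))
    log = RunLog()
    try:
        for trig in triggers:
            out = controller(int(trig)) if controller is not None else object()
            if out is None:
                continue
            if cfg.mode == "buffered":
                out_t = _buffered_output_sample(int(trig), dT_samp)
            else:
                block_end = (int(trig) // cfg.samples_per_block + 1) * cfg.samples_per_block
                out_t = block_end + delay_samp
            log.records.append(LatencyRecord(
                trigger_time=int(trig), output_time=int(out_t),
                latency=(out_t - trig) / fs))
            log.outputs.append(out)
    except Exception as exc:
        log.aborted = True
        log.diagnostic = f"controller fault at trigger {trig}: {exc}"
    return log


def latency_stats(records: list[LatencyRecord], bin_width: float = 1e-3
                  ) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Mean, SD, and a normalized latency histogram.

    Returns ``(mean_s, sd_s, bin_edges_s, density)`` where the histogram
    bins sum to 1 over the observed range.
    """
    if not records:
        raise ValueError("no latency records")
    lat = np.asarray([r.latency for r in records])
    lo = np.floor(lat.min() / bin_width) * bin_width
    hi = np.ceil(lat.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(lat, bins=edges)
    density = counts / counts.sum()
    return float(lat.mean()), float(lat.std(ddof=0)), edges, density
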