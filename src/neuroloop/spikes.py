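"""Three-step spike filtering: detection, validation, and sorting.

Detection compares each voltage sample against a threshold proportional to a
running RMS estimate of the channel noise; on a crossing, a peak-aligned
snippet is cut from the stream.  Candidate snippets are validated with ad hoc
criteria on peak-to-peak amplitude, slope, and width.  Accepted snippets can
be sorted into putative single units with a Gaussian mixture model fitted on
principal-component projections, with the component count chosen by BIC.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .core import MultiChannelWindow, SpikeEvent

__all__ = [
    "DetectorConfig",
    "ValidationCriteria",
    "SorterModel",
    "RmsState",
    "estimate_rms",
    "detect_spikes",
    "SpikeDetector",
    "validate_spike",
    "fit_sorter",
    "assign_unit",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Threshold-detector settings.

    The threshold on each channel is ``threshold_multiplier * RMS``; the RMS
    is a running exponentially weighted estimate with time constant
    ``rms_window`` seconds.  Snippets span ``snippet_pre`` samples before the
    aligned peak through ``snippet_post`` after it.  ``dead_time`` suppresses
    re-triggering after an accepted event.  Negative-going detection is the
    extracellular default.
    """

    threshold_multiplier: float = 5.0
    rms_window: float = 1.0
    snippet_pre: int = 15     # 0.6 ms at 25 kHz
    snippet_post: int = 35    # 1.4 ms at 25 kHz
    dead_time: int = 25       # 1 ms at 25 kHz
    align_search: int = 25    # samples searched for the extremum after crossing
    polarity: str = "negative"

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be positive")
        if self.dead_time < 0:
            raise ValueError("dead_time must be >= 0")
        if self.polarity not in ("negative", "positive", "both"):
            raise ValueError(f"bad polarity {self.polarity!r}")

    @property
    def snippet_len(self) -> int:
        return self.snippet_pre + self.snippet_post + 1


class RmsState:
    """Carried state for the exponentially weighted running RMS."""

    def __init__(self, n_channels: int):
        self.mean_square = np.zeros(n_channels)
        self.initialized = False


def estimate_rms(spike_band: MultiChannelWindow, window: float = 1.0,
                 state: RmsState | None = None,
                 valid_mask: np.ndarray | None = None) -> np.ndarray:
    """Running RMS voltage per channel.

    Exponentially weighted mean of the squared signal with time constant
    ``window`` seconds, seeded from the first sample so short inputs settle
    quickly.  Returns the estimate at the end of the window; pass ``state``
    to continue across windows.  Where ``valid_mask`` is False (e.g. inside
    stimulus-artifact regions) the estimate holds instead of updating.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    x = spike_band.values
    fs = spike_band.time_base.sample_rate
    beta = float(np.exp(-1.0 / (fs * window)))
    if state is None:
        state = RmsState(x.shape[0])
    ms = state.mean_square.copy()
    from scipy.signal import lfilter
    for ch in range(x.shape[0]):
        xc = x[ch] if valid_mask is None else x[ch, valid_mask[ch]]
        if xc.size == 0:
            continue
        if not state.initialized:
            ms[ch] = xc[0] ** 2
        out, _ = lfilter([1 - beta], [1, -beta], xc ** 2,
                         zi=np.atleast_1d(ms[ch] * beta))
        ms[ch] = out[-1]
    if x.shape[1]:
        state.initialized = True
    state.mean_square = ms
    return np.sqrt(ms)


def detect_spikes(spike_band: MultiChannelWindow, rms: np.ndarray,
                  cfg: DetectorConfig = DetectorConfig()) -> list[SpikeEvent]:
    """Threshold detection with peak alignment and snippet extraction.

    One event per threshold crossing, aligned to the extremum within
    ``align_search`` samples of the crossing; crossings within ``dead_time``
    of an accepted event are suppressed.  Events whose snippet would extend
    past the end of the window are deferred (see :class:`SpikeDetector` for
    the streaming wrapper that recovers them).
    """
    rms = np.asarray(rms, dtype=float)
    if np.any(rms <= 0):
        raise ValueError("rms must be strictly positive")
    x = spike_band.values
    events: list[SpikeEvent] = []
    for ch in range(x.shape[0]):
        thr = cfg.threshold_multiplier * rms[ch]
        if cfg.polarity == "negative":
            crossing = x[ch] < -thr
        elif cfg.polarity == "positive":
            crossing = x[ch] > thr
        else:
            crossing = np.abs(x[ch]) > thr
        idx = np.flatnonzero(crossing)
        last_accept = -np.inf
        for i in idx:
            if i - last_accept <= cfg.dead_time:
                continue
            if i < cfg.snippet_pre:
                continue  # cannot cut a full snippet before the stream start
            seg_end = min(i + cfg.align_search + 1, x.shape[1])
            seg = x[ch, i:seg_end]
            if cfg.polarity == "positive":
                peak = i + int(np.argmax(seg))
            elif cfg.polarity == "negative":
                peak = i + int(np.argmin(seg))
            else:
                peak = i + int(np.argmax(np.abs(seg)))
            if peak + cfg.snippet_post >= x.shape[1]:
                continue  # deferred: snippet incomplete in this window
            snip = x[ch, peak - cfg.snippet_pre: peak + cfg.snippet_post + 1].copy()
            events.append(SpikeEvent(
                time=spike_band.start_sample + peak,
                channel=ch,
                waveform=snip,
                threshold_at_detection=thr,
            ))
            last_accept = peak
    events.sort(key=lambda e: (e.time, e.channel))
    return events


class SpikeDetector:
    """Streaming detector: chunked processing equals batch processing.

    Keeps a tail of ``snippet_pre + align_search + snippet_post`` samples so
    events near chunk boundaries are emitted once their snippet is complete.
    """

    def __init__(self, n_channels: int, cfg: DetectorConfig = DetectorConfig()):
        self.cfg = cfg
        self.n_channels = n_channels
        self._carry: np.ndarray | None = None
        self._carry_start = 0
        self._emitted_until = -np.inf

    def process(self, window: MultiChannelWindow, rms: np.ndarray) -> list[SpikeEvent]:
        cfg = self.cfg
        overlap = cfg.snippet_pre + cfg.align_search + cfg.snippet_post + cfg.dead_time + 1
        if self._carry is None:
            vals = window.values
            start = window.start_sample
        else:
            vals = np.concatenate([self._carry, window.values], axis=1)
            start = self._carry_start
        combined = MultiChannelWindow(start, vals, window.time_base)
        events = detect_spikes(combined, rms, cfg)
        # only emit events whose snippet cannot change with future samples
        safe_until = combined.end_sample - (cfg.align_search + cfg.snippet_post + 1)
        out = [e for e in events
               if e.time < safe_until and e.time > self._emitted_until]
        if out:
            self._emitted_until = max(e.time for e in out)
        keep = min(vals.shape[1], overlap)
        self._carry = vals[:, vals.shape[1] - keep:].copy()
        self._carry_start = combined.end_sample - keep
        return out


@dataclass(frozen=True)
class ValidationCriteria:
    """Ad hoc waveform acceptance bounds (volts / samples)."""

    min_p2p: float
    max_p2p: float
    max_slope: float
    min_width: int
    max_width: int

    def __post_init__(self) -> None:
        if not self.min_p2p < self.max_p2p:
            raise ValueError("need min_p2p < max_p2p")
        if not self.min_width < self.max_width:
            raise ValueError("need min_width < max_width")


def validate_spike(event: SpikeEvent, criteria: ValidationCriteria) -> bool:
    """Accept a snippet iff peak-to-peak, max slope, and width-at-half-peak
    all fall within the configured bounds.  Sign-flip invariant."""
    w = event.waveform
    if w is None:
        raise ValueError("event has no waveform snippet")
    p2p = float(w.max() - w.min())
    if not (criteria.min_p2p <= p2p <= criteria.max_p2p):
        return False
    if np.max(np.abs(np.diff(w))) > criteria.max_slope:
        return False
    peak_idx = int(np.argmax(np.abs(w)))
    peak = w[peak_idx]
    above = np.abs(w) >= abs(peak) / 2
    # width of the half-peak region containing the peak
    left = peak_idx
    while left > 0 and above[left - 1]:
        left -= 1
    right = peak_idx
    while right < len(w) - 1 and above[right + 1]:
        right += 1
    width = right - left + 1
    return criteria.min_width <= width <= criteria.max_width


@dataclass
class SorterModel:
    """PCA projection + Gaussian mixture over snippet feature space."""

    pca: PCA
    gmm: GaussianMixture
    n_units: int
    trained_on: int
    snippet_len: int

    @property
    def weights(self) -> np.ndarray:
        return self.gmm.weights_


def fit_sorter(snippets: np.ndarray, max_units: int = 5, seed: int = 0,
               n_components: int = 3, n_restarts: int = 5) -> SorterModel:
    """Fit the automatic spike sorter.

    Snippets (``n_snippets x snippet_len``) are projected onto their first
    ``n_components`` principal components; Gaussian mixtures with 1 through
    ``max_units`` components are fitted with ``n_restarts`` restarts each and
    the component count is chosen by BIC.  Deterministic under a fixed seed.
    """
    snippets = np.asarray(snippets, dtype=float)
    if snippets.ndim != 2:
        raise ValueError("snippets must be 2-D (n_snippets, snippet_len)")
    if snippets.shape[0] < 10 * max_units:
        raise ValueError(
            f"need >= {10 * max_units} snippets to consider {max_units} units, "
            f"got {snippets.shape[0]}"
        )
    if np.allclose(snippets, snippets[0]):
        warnings.warn("all snippets identical; fitting a single-unit model")
        max_units = 1
    d = min(n_components, snippets.shape[1], snippets.shape[0])
    pca = PCA(n_components=d, random_state=seed).fit(snippets)
    feats = pca.transform(snippets)
    best = None
    best_bic = np.inf
    for k in range(1, max_units + 1):
        gmm = GaussianMixture(
            n_components=k, n_init=n_restarts, random_state=seed,
            covariance_type="full", reg_covar=1e-9 * max(feats.var(), 1e-30),
        ).fit(feats)
        bic = gmm.bic(feats)
        if bic < best_bic:
            best, best_bic = gmm, bic
    return SorterModel(pca=pca, gmm=best, n_units=best.n_components,
                       trained_on=snippets.shape[0],
                       snippet_len=snippets.shape[1])


def assign_unit(model: SorterModel, event: SpikeEvent) -> SpikeEvent:
    """Label an event with the maximum-posterior mixture component.

    Ties break deterministically to the lower label.  Returns a copy of the
    event with ``unit`` set.
    """
    w = event.waveform
    if w is None or len(w) != model.snippet_len:
        raise ValueError(
            f"snippet length {None if w is None else len(w)} does not match "
            f"training length {model.snippet_len}"
        )
    feats = model.pca.transform(w[None, :])
    post = model.gmm.predict_proba(feats)[0]
    label = int(np.argmax(post))  # argmax takes the first (lowest) on ties
    return event.with_unit(label)
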