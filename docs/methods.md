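# Methods

This note documents the models implemented in `neuroloop`, the parameters
that matter, the synthetic-data generators used to exercise them, and the
numerical choices made where the design was genuinely open. No empirical
number is stated here that the test suite or `scripts/acceptance.py` does
not itself compute.

## Time and data model

All streams are sample-clocked: time is an integer absolute sample index,
and seconds are derived views (`TimeBase`). Raw and spike-band streams
default to 25 kHz; the LFP stream to 2 kHz (500 µs period). Window ranges
are half-open `[start, end)` everywhere, and event lists are ordered by
`(time, channel)` with deterministic tie-breaking so identical seeds give
bit-identical runs.

## Filter cascade

Band filters are causal Butterworth IIR filters (`scipy.signal.butter`,
default order 2), applied with carried second-order-section state so that
chunked streaming exactly equals filtering the concatenated signal.
Zero-phase filtering (`causal=False`) is an offline option only. The LFP
path decimates after filtering by index mapping
`idx = floor(i · in_rate / out_rate)`, which handles non-integer rate
ratios (25 kHz → 2 kHz is a factor of 12.5) and relies on the band filter
itself for anti-aliasing. MUA is the rectified spike band low-passed at
20 Hz. Common referencing subtracts `scale ×` the across-channel mean or
median; `scale` defaults to 1 and is exposed rather than guessed.

## Stimulus-artifact subtraction (SALPA-style)

Post-stimulus artifacts are removed by subtracting a locally fitted cubic
polynomial — Savitzky–Golay smoothing with window `2·half_width + 1`
samples — from the segment following each pulse, starting at the first
non-saturated ("pegged") sample. Two numerical choices matter:

* **Window length.** The default is `half_width = 37` samples (≈ ±1.5 ms at
  25 kHz). A design study on rail-clipped exponential tails (1 ms decay)
  showed the ±1.5 ms cubic window tracks the tail to < 0.5% of the
  amplifier rail while preserving ≈ 94% of a sub-millisecond spike's
  amplitude; a ±3 ms window leaves ~3%-of-rail residuals exactly where
  early post-stimulus spikes must be detected.
* **Two-pass fitting.** A single fit is dragged by any spike riding on the
  tail (the spike subtracts itself, costing ~5–15% of its amplitude near
  the window edge). The implementation therefore fits once, flags samples
  whose residual exceeds 4× a robust noise scale (median absolute
  deviation), replaces them by linear interpolation from their neighbours,
  and refits. Spikes then survive subtraction nearly unattenuated.

Samples within `blank_len` (default 2 ms) of the onset and pegged samples
(default threshold 95% of the rail) are zeroed and flagged invalid in the
returned mask; downstream RMS estimation holds (does not update) across
masked samples. Outside artifact segments the trace passes through
untouched; nothing later than `fit_len` (default 20 ms) after an onset is
modified.

## Spike pipeline

The channel noise level is a running exponentially weighted RMS (time
constant 1 s by default), seeded from the first sample; thresholds are
`5 × RMS`, negative-going by extracellular convention. On a crossing the
extremum within a 1 ms search window becomes the alignment point and a
snippet (0.6 ms pre / 1.4 ms post) is cut; a 1 ms dead time suppresses
re-triggering. Validation applies ad hoc bounds on peak-to-peak amplitude,
maximum slope, and width at half peak, and is invariant to sign flips.
Sorting projects snippets onto 3 principal components and fits Gaussian
mixtures with 1…`max_units` components (5 restarts each), selecting the
component count by BIC; assignment is maximum posterior with ties broken
to the lower label. The sorter is validated on synthetic clusters with
known labels only — it makes no claim of matching any particular
commercial or published sorter's internals.

## Population firing-rate clamp

The control law multiplies, every `ΔT`, each electrode voltage by
`1 − α(⟨f_u⟩/f* − 1)`; the linearized loop has time constant
`τ_FB = ΔT/α` (verified in simulation to within 20% on a linear plant).
Default settings: `ΔT = 10 ms`, `α = 0.002` (so `τ_FB = 5 s`),
`f* = 3 Hz/unit`, rectangular 2 s rate window, 10 stimulation electrodes
at 1 Hz each in a random repeating sequence (one permutation drawn per run
and repeated, so every electrode fires exactly once per 1 s block).

Open choices, decided as follows:

* **Tuning factors** are `1/(1 + count)` of evoked spikes in the 30 ms
  post-pulse window, normalized to mean 1 — the `+1` regularizes silent
  electrodes, and mean-1 normalization leaves the average drive unchanged.
  They are recomputed every 60 s from rolling counts (no cadence is
  prescribed by the design; 60 s is slow enough not to interact with
  `τ_FB`).
* **Voltage limits**: `v` is clipped to `[0, 1 V]` (pulse amplitudes in
  this regime are at most ~1 V) and initialized at `0.5 · v_max`.
* **Rate window shape**: rectangular; the per-unit rate uses the unit count
  fixed at run start.
* **Open-loop mode** freezes the voltage updates but continues the
  scheduled stimulation unchanged, which is exactly the comparison used to
  show why feedback is needed under drifting excitability.

## Line-length seizure detector

Increments `l_k[t] = |x_k[t] − x_k[t−T_s]|` feed two first-order
exponential averages (`τ = 1 s`, `60 s`; update
`L ← l + e^{−T_s/τ}(L − l)`); detection requires the strict inequality
`L^{1s} > 2·L^{60s}` on ≥ 4 of 16 channels at a single sample. Decisions
taken where the design was open:

* **Initialization**: both averages are seeded to the first computed
  increment, so the ratio starts at 1 rather than ∞.
* **Warm-up**: detections are suppressed for the first `τ_slow` (60 s)
  while the long average converges; without this the slow average's
  start-up transient satisfies the criterion spuriously.
* **Edge-triggered re-arm**: a detection fires only on a false→true
  transition of the multichannel criterion; after a detection (and its
  freeze window) the detector re-arms once the criterion has released.
  This reports an ongoing event once instead of repeatedly.
* **Freeze**: during the response program plus a 1 s post-stimulus guard
  the averages are held bit-identical (the raw `x_prev` still tracks), and
  detection is suppressed.

The vectorized batch detector (`run_detector`, IIR filtering between
detections) is tested sample-for-sample equivalent to the per-sample
`step` primitive, including freeze and warm-up handling. The responsive
program stimulates 10 electrodes chosen without replacement, cycling
sequentially at 45 Hz aggregate for 10 s (450 pulses, biphasic 1 V,
400 µs/phase). No claim about therapeutic effect is made or tested.

## Loop engines

Both executors run in simulated time. In buffered (double-buffered) mode,
control decisions are made at buffer-swap instants and committed output
begins at the *next* swap, so a trigger arriving exactly on a swap incurs
one period `dT` of latency and any later trigger between `dT` and `2·dT` —
the structural signature of block-committed output. Event-driven mode
emits at the end of the data block containing the trigger plus an optional
processing delay, and is strictly faster on identical trigger streams
whenever that delay is below `dT`. Wall-clock latencies of any physical
implementation are out of scope; only the ordering and bounds are modeled.

## Synthetic plant and generators

The culture plant is phenomenological: it exists to exercise controllers
and detectors, not to model biophysics.

* **Spontaneous firing**: homogeneous Poisson at `baseline_rate`
  (default 1 Hz/unit) across 30 units on 59 electrodes, plus compound
  bursts (6/min; every unit fires 1–4 spikes within 200 ms) supplying the
  population synchrony a clamp has to fight.
* **Excitability drift**: geometric Ornstein–Uhlenbeck — log-excitability
  mean-reverts with `τ = 120 s` and stationary SD 0.5, mean-corrected so
  the expected multiplier is 1. This is the minutes-scale, factor-of-~e^±0.5
  variability that makes open-loop stimulation drift off target; it scales
  spontaneous and evoked firing alike. An optional step multiplier at a
  given time models an acute pharmacological perturbation as a pure
  excitability change.
* **Evoked responses**: for a pulse of amplitude `v` on electrode `k`,
  every unit fires independently with probability
  `p_max · sigmoid(slope_k (v − v50_k)) · excitability` (defaults:
  `p_max = 0.6`, `v50 ~ U(0.3, 0.6) V`, `slope ~ U(4, 8) V⁻¹`) at a
  latency uniform in (0, 30 ms]; a zero-amplitude pulse evokes nothing.
  With 10 pulses/s this gives the controller authority from ~1.25 Hz/unit
  (spontaneous) up to ~7 Hz/unit, comfortably spanning the 1.5–4.5 Hz/unit
  setpoint range.
* **Seizure-like LFP**: 16 channels of low-pass (100 Hz) Gaussian noise at
  50 µV RMS; within an epoch the amplitude is multiplied by the configured
  gain and an oscillation at the dominant frequency (default 8 Hz) is
  added, raising the per-sample line length in exactly the way the
  detector measures.
* **Artifact traces**: background noise 10 µV RMS; each stimulus jumps to
  3× the amplifier rail (rail 0.3 mV input-referred, a realistic
  full-scale for a high-gain MEA front end, here 30× the noise RMS),
  clipped at the rail (pegged ≈ 1.1 ms), decaying exponentially with 1 ms
  time constant on top of a small smooth settling term; template spikes
  (biphasic, ~0.2 ms trough) are injected at specified times and
  amplitudes, with ground truth flagging spikes inside the clipped region
  as unrecoverable.

**What the generators do not emulate** — and hence what passing tests do
not show about real recordings: spike waveform overlap and electrode
cross-talk, non-stationary noise, unit appearance/disappearance,
plasticity or any activity-dependent change in the dose-response, real
ictal LFP morphology (the seizure epochs are amplitude/frequency
surrogates), and the biology of pharmacological manipulations (modeled
only as an excitability step). Quantities that depend on living tissue —
e.g. the magnitude of the open-/closed-loop error ratio — are checked only
for ordering, not magnitude, on this plant.

## Problem sizes and tolerances

Closed-loop validation uses 10-simulated-minute epochs (60 000 control
steps) across 5–10 seeds; seizure specificity uses ten 10-minute baseline
recordings; artifact recoverability uses 100 stimuli per latency on a
0.5–10 ms grid; sorter validation uses 20 seeded two-cluster problems at
10σ separation. These sizes give standard errors comfortably inside the
asserted tolerances (e.g. ±10% on the clamped rate) while keeping the full
suite fast. Closed-form checks (feedback time constant, exponential-average
step response, rectified-sine mean, sine RMS) are asserted at 10⁻⁶–2%
depending on whether the quantity is exact or carries an estimator
transient.
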