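# neuroloop

A hardware-free toolkit for **closed-loop multichannel electrophysiology**:
the signal chain and feedback controllers used when a multielectrode array
(MEA) both records from and stimulates neural tissue in real time, re-cast
as deterministic, simulated-time Python so that controllers and detectors
can be developed and validated against a synthetic neural-culture plant
before they ever touch an amplifier.

It is aimed at neuroengineers building closed-loop MEA experiments
(firing-rate clamps, responsive stimulation) and at methods developers who
need a reproducible substrate for benchmarking spike detection, artifact
suppression, or seizure-detection logic.

## What is in the box

| Module | Contents |
| --- | --- |
| `neuroloop.core` | sample-clocked time base, multichannel circular buffers, spike/stimulus/digital event types |
| `neuroloop.filters` | spike band (~200–5000 Hz), LFP band (~1–500 Hz) with decimation, MUA (rectify + low-pass), mean/median common reference, SALPA-style stimulus-artifact subtraction |
| `neuroloop.spikes` | running-RMS threshold detection with peak-aligned snippets, ad hoc waveform validation, PCA + Gaussian-mixture sorting with BIC model selection |
| `neuroloop.clamp` | multichannel population firing-rate clamp, per-electrode tuning factors, random repeating and Poisson stimulus schedulers, pairwise rate correlations |
| `neuroloop.seizure` | line-length seizure detector (dual exponential averages), freeze-during-stimulation, responsive stimulation program |
| `neuroloop.engine` | double-buffered (commit-at-swap) and event-driven loop executors with latency accounting |
| `neuroloop.plant` | synthetic culture plant (spontaneous + bursting firing, drifting excitability, sigmoid dose-response), seizure-like LFP, artifact-contaminated raw traces |
| `neuroloop.streamio`, `neuroloop.cli` | stream-file persistence with CSV mirrors; `neuroloop` command-line entry points |

## The control law

The firing-rate clamp adjusts the amplitude `v_k` of voltage-controlled
biphasic pulses on each stimulation electrode `k` every loop period `ΔT`:

```
v_k[t + ΔT] = v_k[t] − α · v_k[t] · (⟨f_u[t]⟩ / f* − 1)
```

where `⟨f_u[t]⟩` is the average per-unit firing rate over a trailing 2 s
window, `f*` the setpoint, and `α` the gain. The closed loop behaves as a
first-order system with time constant `τ_FB = ΔT / α` (10 ms / 0.002 = 5 s
at the default settings). Electrode voltages are additionally scaled by
tuning factors `∝ 1 / (1 + evoked-spike count in 30 ms)` that equalize
electrode efficacy.

The seizure detector tracks, per LFP channel, the line-length increment
`l_k[t] = |x_k[t] − x_k[t − T_s]|` through two exponential averages
(`τ = 1 s` and `60 s`) and declares a seizure when
`L_k^1s > 2 · L_k^60s` simultaneously on ≥ 4 of 16 channels, freezing the
averages while the responsive stimulation program (10 random electrodes,
45 Hz aggregate, 10 s) runs.

## Worked example

```python
import numpy as np
from neuroloop.plant import CultureParams, make_culture
from neuroloop.clamp import ClampParams, run_clamp

plant = make_culture(CultureParams(), seed=1)
params = ClampParams()          # ΔT = 10 ms, α = 0.002, f* = 3 Hz/unit
traj = run_clamp(plant, params, duration=600.0, seed=1)
second_half = traj.f_avg[len(traj.f_avg) // 2:]
print(f"mean rate, final 5 min: {second_half.mean():.2f} Hz/unit")
print(f"mean stimulation voltage: {traj.mean_v[-1]:.3f} V")
```

prints

```
mean rate, final 5 min: 3.00 Hz/unit
mean stimulation voltage: 0.240 V
```

i.e. the clamp holds the network at the 3 Hz/unit setpoint over the final
five minutes of a ten-minute epoch while the plant's excitability drifts;
the mean drive on the ten stimulation electrodes ends near 0.24 V (it moves
continuously as the controller compensates the drift).
Freezing the voltages halfway through (`open_loop_after=300.0`) leaves the
same stimulation running open-loop; the tracking error then grows because
nothing compensates the drift — compare the two halves of `traj.f_avg`.

A command-line interface wraps the same machinery, e.g.:

```sh
neuroloop clamp --duration 600 --seed 1 --out clamp_out
neuroloop simulate seizure-lfp --duration 90 --seed 2 --out sz
neuroloop detect-seizures --lfp sz/lfp.nls --events-out detections.csv
neuroloop benchmark-latency --mode buffered --dt 0.01
```

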