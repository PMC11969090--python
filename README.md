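# mrgating

Commissioning analyses for MR-guided respiratory beam gating, as a reusable,
tested Python library with a thin CLI.

When an MR-Linac gates the treatment beam on real-time cine MRI tracking of a
moving target, the medical physicist commissioning the system has to answer a
chain of questions: how accurately does the tracker predict the target
position, how large (and how early or late) is the beam on/off latency, does
gating perturb the beam output and profile shape, and what do latency and
tracking error do to the delivered dose distribution?  This package simulates
the whole measurement chain on synthetic data — a programmable breathing
phantom, a cine-rate predictive tracker surrogate, and a latency-injected
binary beam signal — and implements the analyses used to answer those
questions, each validated against independent oracles.

## What it computes

* **Breathing traces** — regular breathing as z(t) = A·sin²ᵖ(πt/T) (the
  cos⁶ respiratory model at p = 3) at 10/14/18 BPM with A = 30 mm, and an
  irregular trace whose rate (U(10, 14) BPM), amplitude (U(26, 30) mm) and
  waveform power are re-drawn every cycle; a rotational-arm kinematic model
  couples the longitudinal drive into lateral/vertical target motion.
* **Tracking accuracy** — per-axis predictive error statistics
  (mean |e|, SD, P95, fraction within 1/2 mm) on non-inhibited cine frames,
  plus the expanded measurement-uncertainty budget
  k·√((pixel/√3)² + u_stage²) per axis.
* **Beam latency** — threshold crossings of the zero-latency ideal gate
  paired with recorded beam transitions; signed statistics with the
  early (pre-emptive, negative) / late (positive) decomposition, P95 of
  |latency| and tolerance fractions.
* **Zero-latency reference dose** — the time-weighted convolution
  D_ref(x, z) = Σᵢ D_static(x, z + Δzᵢ)·δtᵢ / Σᵢ δtᵢ over the beam-on
  sub-intervals, displacements clamped to the gating window.
* **Profile constancy** — film-scan preprocessing (red channel, median
  filter), rigid fiducial registration, band-averaged profiles, and the
  CAX / field size / 80–20 penumbra / flatness / symmetry metrics.
* **Gamma analysis** — global 2D gamma (dose tolerance % of the reference
  maximum, DTA in mm, low-dose threshold), evaluated at reference points
  with an exactly-truncated search over a finely resampled evaluated grid.

## Worked example

Measure injected beam latency on a 10 BPM trace gated at ±5 mm:

```python
import numpy as np
from mrgating import (GatingConfig, generate_regular_trace, ideal_gate_signal,
                      delay_transitions, detect_events, latency_statistics,
                      uncertainty_budget)

trace = generate_regular_trace(rate_bpm=10, amplitude_mm=30, power=3,
                               duration_s=600, fs=100)
cfg = GatingConfig(thresholds={"z": (-5.0, 5.0)})
ideal = ideal_gate_signal(trace, cfg, fs=2000)      # zero-latency gate, 2 kHz

rng = np.random.default_rng(0)                       # inject N(0, 60 ms) delays
beam = delay_transitions(ideal, rng=rng, on_sd_s=0.06, off_sd_s=0.06)

stats = latency_statistics(detect_events(trace, beam, cfg))
for kind, s in stats.items():
    print(f"{kind}: n={s.n_events} mean={s.mean_ms:+.1f} ms (SD {s.sd_ms:.1f}) "
          f"P95={s.p95_ms:.1f} ms  <=100 ms: {100*s.frac_within[100.0]:.1f}%")

budget = uncertainty_budget(pixel_mm=1.13,
                            stage_precision_mm={"x": 0.25, "y": 0.5, "z": 0.25},
                            coverage_k=2)
print("expanded uncertainty (mm):", budget.expanded_mm)
```

prints

```
beam-on: n=100 mean=+5.1 ms (SD 58.0) P95=108.5 ms  <=100 ms: 92.0%
beam-off: n=100 mean=-2.8 ms (SD 57.6) P95=114.1 ms  <=100 ms: 93.0%
expanded uncertainty (mm): {'x': 1.4, 'y': 1.64, 'z': 1.4}
```

One beam-on and one beam-off gating event occur per breathing cycle (100
each over 10 minutes); the recovered mean is statistically zero and the SD
matches the injected 60 ms, so roughly 92% of events land within the 100 ms
tolerance.  The uncertainty budget combines the 1.13 mm cine pixel
(rectangular distribution) with the stage precision at k = 2.

The full commissioning run — tracking accuracy, latency, and the dosimetric
gamma comparison of a simulated gated delivery against its zero-latency
convolution reference — is available from the shell:

```sh
mrgating report --seed 0 --outdir out/
```

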