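# Methods

This note documents the models behind `mrgating`, the choices made where the
design was genuinely open, and what the synthetic studies do and do not show
about real hardware.

## Breathing-trace model

Regular breathing is z(t) = A·sin²ᵖ(πt/T) with period T = 60/rate.  The
exhale baseline is fixed at 0 mm and the inhale peak at A, so cycle
boundaries sit at the rest position; this makes a gating window anchored at
0 mm (e.g. the 0–15 mm window covering half of a 30 mm amplitude)
well-defined.  Whether a phase offset is applied (starting at inhale rather
than exhale) affects no duty-cycle-invariant statistic, so the baseline
convention was chosen for definiteness.

The irregular trace concatenates cycles whose rate, amplitude and waveform
power (p ∈ {1, 2, 3}, i.e. cos²/cos⁴/cos⁶) are re-drawn independently per
cycle from uniform distributions (10–14 BPM, 26–30 mm by default).  Each
cycle's duration is snapped to the sample grid so that boundaries coincide
with samples and the trace is exactly 0 there — continuity is guaranteed by
construction rather than by cross-fading, since every waveform in the
family starts and ends at zero.  The snapping error is at most half a
sample (5 ms at the default 100 Hz), i.e. below 0.02 BPM on a cycle.

The phantom's rotational arm is modelled as a linear map of the
longitudinal position onto the arm angle, θ(t) = θ_max·(2z/A_ref − 1) with
θ_max = 30° over A_ref = 30 mm, and a target offset r = 15 mm from the
rotation axis: x = r·sinθ − r·sinθ₀, y = r·cosθ − r·cosθ₀.  The vendor's
actual phase relationship is proprietary; the linear map is a surrogate and
is fully configurable (`KinematicsConfig`).

Sampling rates: 100 Hz for motion traces (the encoder scale), 2000 Hz for
beam signals (the unfiltered analog latency channel).

## Tracking and gating surrogate

The imaging/template-matching chain is replaced by a positional surrogate:
the true target position is sampled at the cine interval (0.2 s, 5 fps),
optionally extrapolated ahead by the system processing delay with a
least-squares line through the last `history` frames (default 2), and
perturbed with independent per-axis Gaussian noise (default SD 0.3 mm,
consistent with sub-millimetre per-axis tracking).  Frames during the
initial learn period are flagged inhibited and force the beam off, matching
the tracker's model-building phase.

Gating rules: a per-axis displacement threshold with *inclusive* bounds
(ties resolve toward treating), or a volumetric-overlap rule computing the
fraction of a spherical target inside the envelope box on a voxel grid of
step radius/50 (bias well below the 0.01 accuracy the tests demand).

Beam control evaluates the permit once per frame.  Each permit change
schedules a transition at the decision time plus a draw from the
configured on/off delay distribution.  With the linear predictor the
transition is scheduled at `frame_t + system_delay − cine_interval/2`: the
prediction bridges the processing delay, and the half-frame offset centres
the residual 5 fps quantization so the chain's mean latency is set by the
delay distribution alone.  Without this centring every transition would be
systematically early by ~half a frame, which contradicts the near-zero
mean latencies a latency-compensating tracker achieves; with it, the
simulated chain produces means within a few ms of zero, SDs near the
injected 60 ms, and both pre-emptive and delayed events — the observed
phenomenology of such systems.  Overlapping transitions (a delay outlasting
the next permit interval) resolve in favour of the later event.  A single
RNG stream keyed by the config seed drives noise (frame order) then delays
(event order), making deliveries bit-reproducible.

`delay_transitions` additionally supports signal-level latency injection —
shifting each transition of an existing (e.g. ideal) gate — which is the
ground-truth-controlled route used for latency-recovery studies, where the
cine chain itself is not under test.

## Latency analysis

Threshold crossings come from the zero-latency ideal gate of the *true*
motion, evaluated at the beam signal's rate (0.5 ms resolution).  Each
crossing is paired with the nearest same-direction beam transition within
± half the minimum inter-crossing interval; the window prevents cross-cycle
mispairing on fast traces (at 10 BPM it is ≈ 1.4 s, far above any realistic
latency).  Unpaired crossings/transitions are reported but excluded from
statistics, as are crossings during the learn period.  Statistics per
transition type: signed mean and SD, the means of the negative
(pre-emptive) and positive (delayed) subsets — reported as absent, never
zero, when a subset is empty — the 95th percentile of |latency| (linear
interpolation between order statistics), and fractions within 100/200 ms.

## Tracking-accuracy statistics

Errors are predicted − true per axis at frame times (truth linearly
interpolated; the study logs share one clock), inhibited frames excluded.
Per axis the mean, P95 and threshold fractions are computed on |error| and
the SD on the signed error; the vector row uses the Euclidean norm
throughout.  The signed-SD choice makes the statistics invertible: injected
zero-mean Gaussian noise of SD σ is recovered at σ (the SD of |error| for a
half-normal would be 0.60σ and would not be).

The uncertainty budget treats the tracker's spatial resolution as a
rectangular distribution spanning the in-plane cine pixel,
u_track = pixel/√3, combined in quadrature with the stage's per-axis
precision and expanded by the coverage factor k.  With a 1.13 mm pixel,
0.25/0.5/0.25 mm stage precision and k = 2 this gives 1.40/1.64/1.40 mm
(x/y/z); the pixel size (not half of it) is the rectangular half-width, the
only reading consistent with those values, and the slice thickness does not
enter.

## Zero-latency reference dose

D_ref(x, z) = Σᵢ D_static(x, z + Δzᵢ)·δtᵢ / Σᵢ δtᵢ over the beam-on
sub-intervals of the signal.  One segment is formed per beam-on sample
interval; its displacement is the trace interpolated at the interval
midpoint (the choice of midpoint vs endpoint is below the sample period in
effect).  Shifts use linear interpolation with zero fill outside the grid.
Displacements outside the gating window are clamped to the nearest bound —
the window confines the spatial range of the convolution, and residual
out-of-window excursions (from latency) are small; passing `window=None`
disables clamping, which is how the dose actually accumulated by a
latency-affected delivery is modelled.  For long 2 kHz deliveries the
displacements can be quantized to 0.01 mm bins, collapsing ~10⁵ segments
to ≤ 1.5×10³ unique shifts with a worst-case 0.005 mm position error —
negligible against the 1 mm grid and 1–2 mm DTA criteria.  Dose is relative
throughout (no absolute calibration is modelled).

The synthetic static field is a separable product of erf edges with the 50%
level at the nominal field borders and Gaussian-like penumbra (σ = 3 mm
default, an 80–20 penumbra of 2√2·erfinv(0.6)·σ ≈ 5.0 mm, typical of a
collimated MV field at depth).  The dosimetric-study geometry is a
40 × 55 mm field centred at z = 7.5 mm, covering a ~30 mm target swept over
the 0–15 mm gating window plus a 5 mm margin, on a 1 mm grid.

## Profile metrics

Profiles are band means (default 5 mm band) over rows/columns of the grid.
CAX is the value at the midpoint between the 50%-of-CAX crossings, found by
a short fixed-point iteration seeded at 50% of the maximum; field size is
the crossing distance (linear interpolation); penumbrae are per-side
80→20%-of-CAX distances; flatness is 100·(max−min)/(max+min) and symmetry
the maximum mirrored |L−R| in % of CAX, both over the central 80% of the
field.  These are the common variation definitions; vendor analysis
software does not publish its formulas, so deltas between gated and ungated
profiles (the constancy quantities) are the meaningful outputs, not the
absolute flatness/symmetry values.

Film preprocessing takes the scanner's red channel, applies a square median
filter (edge-replicated borders), and maps pixels to the dose grid by the
scan spacing.  Rigid registration of fiducial marks is least-squares
rotation+translation (Umeyama, no scaling) via scikit-image, with the
residual RMS reported; fiducial coordinates are supplied (manual
identification), not auto-detected.

## Gamma analysis

Global gamma at reference points, searching the evaluated distribution
(Low-style convention): γ² = |r − r_ref|²/DTA² + (D_eval − D_ref)²/tol²,
with tol a percentage of the reference maximum and points below the
low-dose threshold (10% of the reference maximum by default) excluded.  The
evaluated distribution is bilinearly resampled to ≤ DTA/10 and the search
truncated at radius DTA·γ₀, where γ₀ is the candidate at the reference
position — an *exact* truncation, since beyond it the distance term alone
exceeds γ₀.  Passing is inclusive (γ ≤ 1, with a 10⁻⁹ cushion against
float round-off at exact tolerance).  On small grids the implementation
agrees with an exhaustive brute-force search to machine precision; the
0.01 test tolerance covers the resampling discretization.

## Study sizes and determinism

The bundled studies use per-trace durations of 5 min (tracking accuracy,
≈1500 frames), 11 min (latency, ≥100 events per transition type at the
slowest rate) and 3 min (dosimetric), with the dosimetric delivery at
2 kHz and displacement binning at 0.01 mm; a full report runs in well under
a minute on one core.  Every report embeds the configuration hash and seed,
and identical configurations produce byte-identical CSVs.

## Limitations

* No MR image formation, template matching or registration of cine frames
  is simulated; tracking error is a configurable noise model, so inhibit
  fractions and their dependence on image quality are inputs, not
  predictions.
* The predictor is a linear extrapolation surrogate, not the vendor's
  algorithm; absolute latency/accuracy numbers from hardware are therefore
  not reproduced, only the statistical machinery that measures them
  (validated by parameter-recovery tests).
* Dose modelling is a separable relative field with a z-only motion blur
  (the displacement convolution acts along the longitudinal axis, as the
  reference-dose construction prescribes); there is no fluence/MLC/
  Monte-Carlo engine, no magnetic-field dose effects, and no film
  calibration curve.
* Passing tests demonstrate internal consistency and correct statistics on
  synthetic data with independent per-frame noise; real tracking errors are
  autocorrelated and scene-dependent, so hardware commissioning values will
  differ.
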