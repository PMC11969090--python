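"""Gated beam-delivery simulation: cine-rate tracking, gating decisions,
latency injection and duty-cycle sequences.

The tracking chain of an MR-guided gating system is modelled positionally:
the imaging/template-matching pipeline is replaced by a surrogate that
samples the true target position at the cine frame rate (default 5 frames
per second), optionally extrapolates it ahead by the system processing
delay, and adds Gaussian prediction noise.  Beam control evaluates a gating
rule on each frame's predicted position and applies each permit transition
to a high-rate binary beam signal after drawing a configurable on/off delay.

Two gating rules are provided: a per-axis displacement threshold (beam on
iff every constrained axis is inside its bounds, bounds inclusive) and a
volumetric-overlap rule (beam on iff the fraction of a spherical target
inside the gating envelope stays above a limit).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .traces import MotionTrace

__all__ = [
    "GatingConfig",
    "TrackingLog",
    "BeamSignal",
    "simulate_tracking",
    "gate_decision",
    "overlap_fraction",
    "simulate_gated_delivery",
    "duty_cycle_signal",
    "ideal_gate_signal",
    "delay_transitions",
    "transition_times",
    "write_beam_csv",
    "read_beam_csv",
    "write_tracking_csv",
    "read_tracking_csv",
    "load_gating_config",
    "save_gating_config",
]

#: default high-rate beam-signal sampling rate (Hz); matches a 2 kHz
#: unfiltered analog latency-measurement channel
BEAM_FS_DEFAULT = 2000.0


@dataclass
class GatingConfig:
    """Configuration of the tracking surrogate and beam-control chain.

    Parameters
    ----------
    mode : {'displacement_threshold', 'overlap', 'duty_cycle'}
        Gating rule.
    thresholds : dict
        Per-axis (x/y/z) inclusive bounds in mm for displacement gating.
        The default gates on z in [-5, +5] mm about the reference position
        (latency protocol); dosimetric gating uses ``{"z": (0.0, 15.0)}``.
    overlap_limit : float
        Minimum target/envelope volumetric overlap fraction (overlap mode).
    target_radius : float
        Radius (mm) of the spherical target (overlap mode).
    envelope : dict
        Per-axis envelope box bounds in mm (overlap mode).
    cine_interval : float
        Seconds between cine frames (default 0.2 s, i.e. 5 fps).
    system_delay : float
        Processing delay (s) the predictor extrapolates across.
    predictor : {'none', 'linear'}
        Position predictor surrogate; 'linear' extrapolates from the last
        ``history`` frames, 'none' passes the current frame through.
    history : int
        Number of frames used by the linear predictor (>= 2).
    prediction_noise_sd : float
        Per-axis Gaussian noise (mm) added to each predicted position.
    beam_on_delay, beam_off_delay : (mean_s, sd_s)
        Delay drawn for each permit transition; sd 0 gives a constant delay.
    learn_time : float
        Initial period (s) during which tracking is inhibited.
    seed : int
        Seed of the single RNG stream; draws are consumed in event order.
    """

    mode: Literal["displacement_threshold", "overlap", "duty_cycle"] = "displacement_threshold"
    thresholds: dict = field(default_factory=lambda: {"z": (-5.0, 5.0)})
    overlap_limit: float = 0.95
    target_radius: float = 10.0
    envelope: dict = field(default_factory=dict)
    cine_interval: float = 0.2
    system_delay: float = 0.2
    predictor: Literal["none", "linear"] = "none"
    history: int = 2
    prediction_noise_sd: float = 0.0
    beam_on_delay: tuple[float, float] = (0.0, 0.0)
    beam_off_delay: tuple[float, float] = (0.0, 0.0)
    learn_time: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cine_interval <= 0:
            raise ValueError("cine_interval must be positive")
        if not (0 < self.overlap_limit <= 1):
            raise ValueError("overlap_limit must lie in (0, 1]")
        if self.beam_on_delay[0] < 0 or self.beam_off_delay[0] < 0:
            raise ValueError("mean beam delays must be >= 0")
        if self.history < 2:
            raise ValueError("history must be >= 2")


@dataclass
class TrackingLog:
    """Per-cine-frame predicted target position with inhibit flags."""

    frame_t: np.ndarray  # seconds
    predicted: np.ndarray  # (n, 3) mm
    inhibit: np.ndarray  # bool
    plane: np.ndarray | None = None  # alternating 'cor'/'sag' labels

    def __post_init__(self) -> None:
        self.frame_t = np.asarray(self.frame_t, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.inhibit = np.asarray(self.inhibit, dtype=bool)
        if self.plane is None:
            self.plane = np.where(np.arange(len(self.frame_t)) % 2 == 0, "cor", "sag")
        if not np.all(np.isfinite(self.predicted[~self.inhibit])):
            raise ValueError("predicted positions must be finite where not inhibited")


@dataclass
class BeamSignal:
    """Binary beam state sampled at a fixed rate."""

    t: np.ndarray
    state: np.ndarray
    fs: float = BEAM_FS_DEFAULT

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.state = np.asarray(self.state, dtype=np.int8)
        if self.state.shape != self.t.shape:
            raise ValueError("state and t must have the same length")
        if not np.isin(self.state, (0, 1)).all():
            raise ValueError("state must be binary")

    @property
    def on_fraction(self) -> float:
        return float(np.mean(self.state))


# ---------------------------------------------------------------------------
# tracking surrogate
# ---------------------------------------------------------------------------

def simulate_tracking(
    motion: MotionTrace,
    cfg: GatingConfig,
    rng: np.random.Generator | None = None,
) -> TrackingLog:
    """Sample the motion at cine rate and predict ahead by the system delay.

    The predictor sees the true positions only at frame times.  'linear'
    fits a straight line through the last ``cfg.history`` frames and
    evaluates it ``cfg.system_delay`` ahead of the current frame; frames
    with insufficient history, or earlier than ``cfg.learn_time``, are
    flagged inhibited (their predicted position is the pass-through value).
    Independent Gaussian noise of ``prediction_noise_sd`` mm is added per
    axis.
    """
    if motion.duration < cfg.learn_time + cfg.cine_interval:
        raise ValueError("motion must span learn_time plus at least one frame")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    frame_t = np.arange(0.0, motion.duration + 1e-12, cfg.cine_interval)
    true_at_frames = motion.interp_positions(frame_t)
    n = len(frame_t)
    predicted = true_at_frames.copy()
    inhibit = frame_t < cfg.learn_time

    if cfg.predictor == "linear":
        h = cfg.history
        inhibit = inhibit | (np.arange(n) < h - 1)
        # least-squares line through the last h frames, evaluated
        # system_delay ahead of the current frame
        for k in range(h - 1, n):
            tt = frame_t[k - h + 1 : k + 1]
            pp = true_at_frames[k - h + 1 : k + 1]
            slope, intercept = np.polyfit(tt - tt[-1], pp, 1)
            predicted[k] = intercept + slope * cfg.system_delay
    elif cfg.predictor != "none":
        raise ValueError(f"unknown predictor {cfg.predictor!r}")

    if cfg.prediction_noise_sd > 0:
        predicted = predicted + rng.normal(0.0, cfg.prediction_noise_sd, size=predicted.shape)
    return TrackingLog(frame_t=frame_t, predicted=predicted, inhibit=inhibit)


# ---------------------------------------------------------------------------
# gating rules
# ---------------------------------------------------------------------------

_AXIS = {"x": 0, "y": 1, "z": 2}


def gate_decision(predicted: np.ndarray, cfg: GatingConfig) -> bool | np.ndarray:
    """Beam permit for one position (3-vector) or many ((n, 3) array).

    Displacement mode: permit iff every constrained axis lies within its
    inclusive bounds.  Overlap mode: permit iff the fraction of the target
    sphere (displaced by the predicted position) inside the envelope box is
    at least ``overlap_limit``.
    """
    pos = np.atleast_2d(np.asarray(predicted, dtype=float))
    if cfg.mode == "displacement_threshold":
        ok = np.ones(len(pos), dtype=bool)
        for axis, (lo, hi) in cfg.thresholds.items():
            v = pos[:, _AXIS[axis]]
            ok &= (v >= lo) & (v <= hi)
    elif cfg.mode == "overlap":
        ok = np.array(
            [
                overlap_fraction(p, cfg.target_radius, cfg.envelope) >= cfg.overlap_limit
                for p in pos
            ]
        )
    else:
        raise ValueError(f"gate_decision undefined for mode {cfg.mode!r}")
    return bool(ok[0]) if np.ndim(predicted) == 1 else ok


def overlap_fraction(
    sphere_center: np.ndarray,
    sphere_radius: float,
    box: dict,
) -> float:
    """Fraction of a sphere's volume inside an axis-aligned box.

    Computed on a voxel grid with step radius/50 over the sphere's bounding
    box; ``box`` maps axis labels to (lo, hi) mm, with unconstrained axes
    omitted.
    """
    if sphere_radius <= 0:
        raise ValueError("sphere_radius must be positive")
    c = np.asarray(sphere_center, dtype=float)
    step = sphere_radius / 50.0
    g = np.arange(-sphere_radius + step / 2, sphere_radius, step)
    gx, gy, gz = np.meshgrid(g, g, g, indexing="ij")
    inside_sphere = gx**2 + gy**2 + gz**2 <= sphere_radius**2
    inside_box = np.ones_like(inside_sphere)
    coords = {"x": gx + c[0], "y": gy + c[1], "z": gz + c[2]}
    for axis, (lo, hi) in box.items():
        if lo >= hi:
            raise ValueError(f"degenerate box bounds on axis {axis}")
        v = coords[axis]
        inside_box &= (v >= lo) & (v <= hi)
    n_sphere = int(np.count_nonzero(inside_sphere))
    return float(np.count_nonzero(inside_sphere & inside_box) / n_sphere)


# ---------------------------------------------------------------------------
# beam-signal construction
# ---------------------------------------------------------------------------

def _signal_grid(duration_s: float, fs: float) -> np.ndarray:
    n = int(round(duration_s * fs)) + 1
    return np.arange(n) / fs


def simulate_gated_delivery(
    motion: MotionTrace,
    cfg: GatingConfig,
    beam_fs: float = BEAM_FS_DEFAULT,
) -> tuple[BeamSignal, TrackingLog]:
    """Full gated-delivery chain: tracking, per-frame decision, delayed beam.

    The permit is evaluated once per cine frame on the predicted position
    (off wherever inhibited).  Each permit change schedules a beam
    transition at the decision time plus a delay drawn from the configured
    on/off distribution; transitions are applied to the high-rate signal in
    scheduled order, so if a delay outlasts the next permit interval the
    later transition wins.  A single RNG stream keyed by ``cfg.seed`` drives
    the prediction noise (frame order) and the delay draws (event order).

    With the linear predictor the chain emulates a latency-compensated
    tracker: the prediction bridges the processing delay, and transitions
    are scheduled at ``frame_t + system_delay - cine_interval/2`` plus the
    delay draw, which centres the residual cine-frame quantization so the
    mean latency of the chain is set by the delay distribution alone
    (without the half-frame centring every transition would be
    systematically early by half a frame on average).  With
    ``predictor='none'`` no delay compensation is modelled and transitions
    are scheduled at the frame time itself.
    """
    rng = np.random.default_rng(cfg.seed)
    log = simulate_tracking(motion, cfg, rng=rng)
    permit = gate_decision(log.predicted, cfg) & ~log.inhibit

    sched_offset = (
        cfg.system_delay - cfg.cine_interval / 2.0 if cfg.predictor != "none" else 0.0
    )
    t = _signal_grid(motion.duration, beam_fs)
    state = np.zeros(len(t), dtype=np.int8)
    events: list[tuple[float, int]] = []
    prev = False
    for k in range(len(log.frame_t)):
        if permit[k] != prev:
            mean, sd = cfg.beam_on_delay if permit[k] else cfg.beam_off_delay
            delay = mean if sd == 0 else rng.normal(mean, sd)
            events.append((log.frame_t[k] + sched_offset + delay, int(permit[k])))
            prev = permit[k]
    events.sort(key=lambda e: e[0])
    for when, st in events:
        i = int(np.ceil(when * beam_fs - 1e-9))
        if i < len(state):
            state[max(i, 0) :] = st
    return BeamSignal(t=t, state=state, fs=beam_fs), log


def duty_cycle_signal(
    on_s: float,
    off_s: float,
    duration_s: float,
    fs: float = BEAM_FS_DEFAULT,
) -> BeamSignal:
    """Periodic applet-style gating: on for ``on_s``, off for ``off_s``."""
    if on_s <= 0:
        raise ValueError("on_s must be positive")
    if off_s < 0:
        raise ValueError("off_s must be >= 0")
    t = _signal_grid(duration_s, fs)
    phase = t % (on_s + off_s)
    state = (phase < on_s).astype(np.int8)
    return BeamSignal(t=t, state=state, fs=fs)


def ideal_gate_signal(
    motion: MotionTrace,
    cfg: GatingConfig,
    fs: float = BEAM_FS_DEFAULT,
) -> BeamSignal:
    """Zero-latency reference gate: the rule applied to the *true* positions
    at every signal sample, with no delays, noise or inhibits."""
    if cfg.mode not in ("displacement_threshold", "overlap"):
        raise ValueError("ideal gate requires a positional gating mode")
    t = _signal_grid(motion.duration, fs)
    pos = motion.interp_positions(t)
    permit = gate_decision(pos, cfg)
    return BeamSignal(t=t, state=permit.astype(np.int8), fs=fs)


def transition_times(beam: BeamSignal) -> tuple[np.ndarray, np.ndarray]:
    """(on_times, off_times): sample times at which the state changes."""
    d = np.diff(beam.state.astype(np.int8))
    return beam.t[1:][d == 1], beam.t[1:][d == -1]


def delay_transitions(
    beam: BeamSignal,
    on_delay_s: float | np.ndarray = 0.0,
    off_delay_s: float | np.ndarray = 0.0,
    rng: np.random.Generator | None = None,
    on_sd_s: float = 0.0,
    off_sd_s: float = 0.0,
) -> BeamSignal:
    """Signal-level latency injection: shift every transition by a delay.

    Each on (off) transition is moved by ``on_delay_s`` (``off_delay_s``)
    plus, when a standard deviation and RNG are given, a Gaussian draw;
    per-transition arrays are also accepted.  Negative shifts model
    pre-emptive gating.  Overlapping transitions resolve in favour of the
    later one.  This bypasses the cine chain entirely and is the tool for
    latency-recovery studies where the injected delay is the ground truth.
    """
    on_t, off_t = transition_times(beam)
    ons = np.broadcast_to(np.asarray(on_delay_s, dtype=float), on_t.shape).copy()
    offs = np.broadcast_to(np.asarray(off_delay_s, dtype=float), off_t.shape).copy()
    if rng is not None:
        if on_sd_s > 0:
            ons += rng.normal(0.0, on_sd_s, size=on_t.shape)
        if off_sd_s > 0:
            offs += rng.normal(0.0, off_sd_s, size=off_t.shape)
    events = sorted(
        [(t + d, 1) for t, d in zip(on_t, ons)] + [(t + d, 0) for t, d in zip(off_t, offs)]
    )
    state = np.full(len(beam.t), beam.state[0], dtype=np.int8)
    if events:
        # before the first shifted transition the beam is in the opposite state
        state[:] = 1 - events[0][1]
    for when, st in events:
        i = int(np.ceil(when * beam.fs - 1e-9))
        if i < len(state):
            state[max(i, 0) :] = st
    return BeamSignal(t=beam.t.copy(), state=state, fs=beam.fs)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_beam_csv(beam: BeamSignal, path: str | Path) -> None:
    pd.DataFrame({"t_s": beam.t, "state": beam.state}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_beam_csv(path: str | Path) -> BeamSignal:
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy()
    fs = 1.0 / (t[1] - t[0])
    return BeamSignal(t=t, state=df["state"].to_numpy(), fs=fs)


def write_tracking_csv(log: TrackingLog, path: str | Path) -> None:
    pd.DataFrame(
        {
            "t_s": log.frame_t,
            "x_mm": log.predicted[:, 0],
            "y_mm": log.predicted[:, 1],
            "z_mm": log.predicted[:, 2],
            "inhibit": log.inhibit.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.6f")


def read_tracking_csv(path: str | Path) -> TrackingLog:
    df = pd.read_csv(path)
    return TrackingLog(
        frame_t=df["t_s"].to_numpy(),
        predicted=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        inhibit=df["inhibit"].to_numpy().astype(bool),
    )


def save_gating_config(cfg: GatingConfig, path: str | Path) -> None:
    d = asdict(cfg)
    d["thresholds"] = {k: list(v) for k, v in cfg.thresholds.items()}
    d["envelope"] = {k: list(v) for k, v in cfg.envelope.items()}
    d["beam_on_delay"] = list(cfg.beam_on_delay)
    d["beam_off_delay"] = list(cfg.beam_off_delay)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_gating_config(path: str | Path) -> GatingConfig:
    d = yaml.safe_load(Path(path).read_text())
    for key in ("thresholds", "envelope"):
        if key in d:
            d[key] = {k: tuple(v) for k, v in d[key].items()}
    for key in ("beam_on_delay", "beam_off_delay"):
        if key in d:
            d[key] = tuple(d[key])
    return GatingConfig(**d)
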