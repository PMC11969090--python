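"""Beam-latency event detection and statistics.

Beam latency is the signed time between the target crossing the gating
boundary (computed from the true motion, zero-latency) and the matching beam
state transition on the recorded beam signal.  Negative latency is
pre-emptive (the beam switched before the crossing, as a predictive tracker
can do); positive latency is delayed response.  Statistics are reported per
transition type (beam-on / beam-off): the signed mean and SD over all
events, the means of the negative ("left") and positive ("right") subsets,
the 95th percentile of |latency| as a one-sided bound, and the fraction of
events within 100 and 200 ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gating import BeamSignal, GatingConfig, ideal_gate_signal, transition_times
from .traces import MotionTrace

__all__ = [
    "LatencyEvent",
    "LatencyEventSet",
    "LatencyStats",
    "detect_events",
    "latency_statistics",
    "write_latency_report",
]


@dataclass(frozen=True)
class LatencyEvent:
    type: str  # 'beam-on' | 'beam-off'
    cross_t: float  # ideal threshold-crossing time, s
    beam_t: float  # matched beam transition time, s

    @property
    def latency_ms(self) -> float:
        return (self.beam_t - self.cross_t) * 1000.0


@dataclass
class LatencyEventSet:
    """Paired crossing/transition events plus the unpaired leftovers."""

    events: list[LatencyEvent]
    unpaired_crossings: list[tuple[str, float]]
    unpaired_transitions: list[tuple[str, float]]

    def latencies_ms(self, type_: str | None = None) -> np.ndarray:
        return np.array(
            [e.latency_ms for e in self.events if type_ is None or e.type == type_]
        )


@dataclass
class LatencyStats:
    """Latency summary for one transition type."""

    type: str
    n_events: int
    mean_ms: float
    sd_ms: float
    left_mean_ms: float | None  # negative (pre-emptive) subset
    left_sd_ms: float | None
    right_mean_ms: float | None  # positive (delayed) subset
    right_sd_ms: float | None
    p95_ms: float  # 95th percentile of |latency|
    frac_within: dict[float, float]  # tolerance_ms -> fraction |latency| <= tol


def detect_events(
    motion: MotionTrace,
    beam: BeamSignal,
    cfg: GatingConfig,
) -> LatencyEventSet:
    """Pair ideal gating-threshold crossings with recorded beam transitions.

    Crossings come from the zero-latency ideal gate of the true motion at the
    beam signal's sampling rate.  Each crossing is matched to the nearest
    same-direction beam transition within +/- half the minimum inter-crossing
    interval (which prevents cross-cycle mispairing); each transition is used
    at most once.  Crossings before ``cfg.learn_time`` are excluded, as are
    unpaired crossings/transitions, which are reported separately.
    """
    ideal = ideal_gate_signal(motion, cfg, fs=beam.fs)
    on_cross, off_cross = transition_times(ideal)
    on_beam, off_beam = transition_times(beam)

    all_cross = np.sort(np.concatenate([on_cross, off_cross]))
    if len(all_cross) == 0:
        import warnings

        warnings.warn("no gating-threshold crossings found in motion trace")
        return LatencyEventSet([], [], [])
    window = np.inf if len(all_cross) < 2 else float(np.min(np.diff(all_cross))) / 2.0

    events: list[LatencyEvent] = []
    unpaired_c: list[tuple[str, float]] = []
    unpaired_t: list[tuple[str, float]] = []
    for type_, crossings, transitions in (
        ("beam-on", on_cross, on_beam),
        ("beam-off", off_cross, off_beam),
    ):
        used = np.zeros(len(transitions), dtype=bool)
        for tc in crossings:
            if tc < cfg.learn_time:
                continue
            free = ~used
            if not free.any():
                unpaired_c.append((type_, float(tc)))
                continue
            idx_free = np.flatnonzero(free)
            j = idx_free[np.argmin(np.abs(transitions[idx_free] - tc))]
            if abs(transitions[j] - tc) <= window:
                used[j] = True
                events.append(LatencyEvent(type_, float(tc), float(transitions[j])))
            else:
                unpaired_c.append((type_, float(tc)))
        for j in np.flatnonzero(~used):
            unpaired_t.append((type_, float(transitions[j])))
    events.sort(key=lambda e: e.cross_t)
    return LatencyEventSet(events, unpaired_c, unpaired_t)


def _subset_stats(values: np.ndarray) -> tuple[float | None, float | None]:
    if len(values) == 0:
        return None, None
    return float(np.mean(values)), float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def latency_statistics(
    events: LatencyEventSet,
    tolerances_ms: tuple[float, ...] = (100.0, 200.0),
) -> dict[str, LatencyStats]:
    """Per-type latency statistics (see :class:`LatencyStats`).

    Percentiles use linear interpolation between order statistics.  An empty
    negative (or positive) subset reports its mean/SD as absent (``None``),
    never as zero.
    """
    out: dict[str, LatencyStats] = {}
    for type_ in ("beam-on", "beam-off"):
        lat = events.latencies_ms(type_)
        if len(lat) == 0:
            continue
        left, left_sd = _subset_stats(lat[lat < 0])
        right, right_sd = _subset_stats(lat[lat > 0])
        out[type_] = LatencyStats(
            type=type_,
            n_events=len(lat),
            mean_ms=float(np.mean(lat)),
            sd_ms=float(np.std(lat, ddof=1)) if len(lat) > 1 else 0.0,
            left_mean_ms=left,
            left_sd_ms=left_sd,
            right_mean_ms=right,
            right_sd_ms=right_sd,
            p95_ms=float(np.percentile(np.abs(lat), 95)),
            frac_within={tol: float(np.mean(np.abs(lat) <= tol)) for tol in tolerances_ms},
        )
    return out


def write_latency_report(
    stats_by_trace: dict[str, dict[str, LatencyStats]],
    path: str | Path | None = None,
) -> pd.DataFrame:
    """CSV report: one row per (trace, transition type).

    Columns mirror a commissioning latency table: signed average (SD), the
    left/negative and right/positive subset means (SD), P95 of |latency| and
    the percentage of events within 100 and 200 ms.
    """
    rows = []
    for trace, per_type in stats_by_trace.items():
        for type_, s in per_type.items():
            rows.append(
                {
                    "trace": trace,
                    "type": type_,
                    "n_events": s.n_events,
                    "average_ms": round(s.mean_ms, 1),
                    "sd_ms": round(s.sd_ms, 1),
                    "left_mean_ms": None if s.left_mean_ms is None else round(s.left_mean_ms, 1),
                    "left_sd_ms": None if s.left_sd_ms is None else round(s.left_sd_ms, 1),
                    "right_mean_ms": None if s.right_mean_ms is None else round(s.right_mean_ms, 1),
                    "right_sd_ms": None if s.right_sd_ms is None else round(s.right_sd_ms, 1),
                    "p95_ms": round(s.p95_ms, 1),
                    "pct_within_100ms": round(100 * s.frac_within.get(100.0, np.nan), 1),
                    "pct_within_200ms": round(100 * s.frac_within.get(200.0, np.nan), 1),
                }
            )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
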