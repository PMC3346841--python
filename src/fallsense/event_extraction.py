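"""Mining week-long wear recordings for high-jerk "fall-like" events.

The mining statistic is the per-sample sum over the three axes of squared
successive acceleration differences, smoothed by a centred two-second
running mean.  One candidate is taken per whole recorded hour — the argmax
of the smoothed score within that hour — giving the hard negative class for
the fall-detection task.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signal_io import RATE, is_uniform, resample_uniform
from .synthetic_data import RawRecording

SMOOTH_SECONDS = 2.0
_SMOOTH_SAMPLES = int(SMOOTH_SECONDS * RATE)  # 40


@dataclass(frozen=True)
class EventCandidate:
    """A mined fall-like event: its time and smoothed jerk score (m²/s⁴)."""

    center_time: float
    score: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be non-negative")


def _running_mean(x: np.ndarray, size: int) -> np.ndarray:
    """Centred running mean with symmetric edge reflection, same length as x."""
    left, right = size // 2, size - 1 - size // 2
    padded = np.pad(x, (left, right), mode="symmetric")
    return np.convolve(padded, np.full(size, 1.0 / size), mode="valid")


def jerk_score(rec: RawRecording) -> np.ndarray:
    """Smoothed squared-change score per sample of a uniform 20 Hz recording.

    Raw score at sample i is Σ_axes (a_i − a_{i−1})², defined as 0 at the
    first sample, then smoothed with a centred 2 s (40-sample) running mean.
    """
    if not is_uniform(rec, RATE):
        raise ValueError("jerk_score requires a uniform 20 Hz recording")
    if rec.duration < SMOOTH_SECONDS:
        raise ValueError("recording must span at least 2 s")
    raw = np.zeros(len(rec))
    raw[1:] = np.sum(np.diff(rec.samples, axis=0) ** 2, axis=1)
    return _running_mean(raw, _SMOOTH_SAMPLES)


def split_sessions(rec: RawRecording, max_gap: float = 1.0) -> list[RawRecording]:
    """Split a recording at timestamp gaps > max_gap (battery-off periods)."""
    breaks = np.flatnonzero(np.diff(rec.timestamps) > max_gap) + 1
    pieces = []
    for lo, hi in zip(np.r_[0, breaks], np.r_[breaks, len(rec)]):
        if hi - lo >= 2:
            t0, t1 = rec.timestamps[lo], rec.timestamps[hi - 1]
            ann = [(t, lab) for t, lab in rec.annotations if t0 <= t <= t1]
            pieces.append(RawRecording(rec.timestamps[lo:hi], rec.samples[lo:hi],
                                       subject_id=rec.subject_id, annotations=ann))
    return pieces


def hourly_candidates(uniform: RawRecording) -> list[EventCandidate]:
    """One candidate per whole recorded hour: the per-hour argmax of the score.

    Trailing partial hours yield no candidate; ties break to the earliest
    sample.  The input must already be on the 20 Hz grid.
    """
    score = jerk_score(uniform)
    t = uniform.timestamps
    n_hours = int((t[-1] - t[0]) // 3600.0)
    out = []
    for h in range(n_hours):
        lo = int(np.searchsorted(t, t[0] + 3600.0 * h, side="left"))
        hi = int(np.searchsorted(t, t[0] + 3600.0 * (h + 1), side="left"))
        i = lo + int(np.argmax(score[lo:hi]))  # argmax returns the first maximum
        out.append(EventCandidate(center_time=float(t[i]), score=float(score[i])))
    return out


def extract_fall_like_events(rec: RawRecording) -> list[EventCandidate]:
    """Mine fall-like events from a (possibly irregular, gappy) wear recording.

    The recording is split into contiguous sessions at gaps > 1 s, each
    session resampled to 20 Hz, and one candidate extracted per whole hour
    of each session.  Candidates are returned in time order.
    """
    candidates: list[EventCandidate] = []
    for session in split_sessions(rec):
        if session.duration < 3600.0:
            continue
        candidates.extend(hourly_candidates(resample_uniform(session)))
    if not candidates:
        warnings.warn("no whole recorded hour available; no events mined",
                      stacklevel=2)
    return sorted(candidates, key=lambda c: c.center_time)
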