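"""Synthetic tri-axial accelerometer data: simulated falls and daily-wear streams.

The generator emulates a belt-worn phone on the lower back with the sensor
axes pointing up (x), left (y) and backward (z).  An accelerometer reports
specific force, so at rest the up-axis reads +9.8 m/s².  Falls follow a
four-phase model — quiet stance, freefall, directional impact, lying — with
the gravity direction spherically interpolated from upright to the post-fall
lying orientation.  Daily-wear streams mix quiet postures, walking bouts,
posture transitions and short high-jerk jolts, sampled at a variable
15–25 Hz rate like the phone logger.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

G = 9.8  # specific force magnitude at rest, m/s²

#: raw trial types, in protocol order
RAW_FALL_TYPES = (
    "slip",
    "trip",
    "lateral-left-active",
    "lateral-left-faint",
    "lateral-right-active",
    "lateral-right-faint",
)

#: raw type -> reported 4-class label (active and faint laterals are merged)
MERGED_LABELS = {
    "slip": "slip",
    "trip": "trip",
    "lateral-left-active": "lateral-left",
    "lateral-left-faint": "lateral-left",
    "lateral-right-active": "lateral-right",
    "lateral-right-faint": "lateral-right",
}

FALL_CLASSES = ("slip", "trip", "lateral-left", "lateral-right")

_UP = np.array([1.0, 0.0, 0.0])

#: post-fall lying orientation: which sensor axis carries gravity afterwards.
#: trip -> prone (back up, z reads +9.8); slip -> supine (z reads -9.8);
#: lateral falls load the left/right axis.
LYING_DIRECTION = {
    "slip": np.array([0.0, 0.0, -1.0]),
    "trip": np.array([0.0, 0.0, 1.0]),
    "lateral-left": np.array([0.0, -1.0, 0.0]),
    "lateral-right": np.array([0.0, 1.0, 0.0]),
}


@dataclass(frozen=True)
class FallSimParams:
    """Knobs of the four-phase fall generator (durations in s, accelerations m/s²)."""

    stance_duration: tuple[float, float] = (2.0, 4.0)
    freefall_duration: tuple[float, float] = (0.3, 0.5)
    freefall_magnitude_ceiling: float = 3.0
    impact_duration: tuple[float, float] = (0.1, 0.2)
    impact_peak: tuple[float, float] = (20.0, 35.0)
    lying_duration: tuple[float, float] = (2.0, 4.0)
    sensor_noise_sd: float = 0.3
    faint_descent_scale: float = 2.0
    rate_band: tuple[float, float] = (15.0, 25.0)
    tilt_sd_deg: float = 5.0
    flail_sd: float = 1.5

    def __post_init__(self) -> None:
        for name in ("stance_duration", "freefall_duration", "impact_duration",
                     "lying_duration"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range must be positive and ordered")
        if not self.freefall_magnitude_ceiling < G:
            raise ValueError("freefall_magnitude_ceiling must be below 9.8 m/s²")
        if not self.impact_peak[0] > G:
            raise ValueError("impact_peak must exceed 9.8 m/s²")
        if not self.rate_band[0] < self.rate_band[1]:
            raise ValueError("rate_band must be (low, high) with low < high")


@dataclass(frozen=True)
class ActivitySimParams:
    """Knobs of the daily-wear generator."""

    walk_fraction: float = 0.15
    walk_frequency: float = 2.0  # Hz, step rate seen on the up-axis
    jolt_rate: float = 2.0  # high-jerk events per hour
    rate_band: tuple[float, float] = (15.0, 25.0)
    sensor_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.walk_fraction <= 1.0:
            raise ValueError("walk_fraction must be in [0, 1]")
        if not self.rate_band[0] < self.rate_band[1]:
            raise ValueError("rate_band must be (low, high) with low < high")
        if self.jolt_rate < 0:
            raise ValueError("jolt_rate must be non-negative")


@dataclass
class RawRecording:
    """A timestamped, possibly irregular tri-axial acceleration stream."""

    timestamps: np.ndarray  # (n,) seconds, strictly increasing
    samples: np.ndarray  # (n, 3) m/s², columns x (up), y (left), z (back)
    subject_id: str = "S0"
    annotations: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.timestamps.ndim != 1:
            raise ValueError("timestamps must be one-dimensional")
        if self.samples.shape != (self.timestamps.size, 3):
            raise ValueError("samples must have shape (len(timestamps), 3)")
        if self.timestamps.size >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def __len__(self) -> int:
        return self.timestamps.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RawRecording):
            return NotImplemented
        return (
            np.array_equal(self.timestamps, other.timestamps)
            and np.array_equal(self.samples, other.samples)
            and self.subject_id == other.subject_id
            and self.annotations == other.annotations
        )


@dataclass
class FallTrial:
    """One simulated fall recording with its raw protocol type and merged label."""

    recording: RawRecording
    raw_type: str
    label: str
    subject_id: str


@dataclass
class StudyBundle:
    """All recordings of a simulated study: labelled falls plus wear streams."""

    falls: list[FallTrial]
    wear: list[RawRecording]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _slerp(u: np.ndarray, v: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Spherical interpolation between unit vectors u and v at fractions s (n,)."""
    dot = float(np.clip(np.dot(u, v), -1.0, 1.0))
    theta = np.arccos(dot)
    if theta < 1e-9:
        return np.repeat(u[None, :], len(s), axis=0)
    sin_t = np.sin(theta)
    a = np.sin((1.0 - s) * theta) / sin_t
    b = np.sin(s * theta) / sin_t
    return a[:, None] * u[None, :] + b[:, None] * v[None, :]


def _random_tilt(rng: np.random.Generator, sd_deg: float) -> np.ndarray:
    """Small random rotation matrix modelling imperfect phone/body alignment."""
    angle = np.deg2rad(rng.normal(0.0, sd_deg))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _variable_timestamps(rng: np.random.Generator, duration: float,
                         rate_band: tuple[float, float]) -> np.ndarray:
    """Timestamps from 0 past `duration`, gaps drawn uniformly in [1/hi, 1/lo]."""
    lo, hi = rate_band
    n_est = int(duration * hi) + 16
    gaps = rng.uniform(1.0 / hi, 1.0 / lo, size=n_est)
    t = np.concatenate([[0.0], np.cumsum(gaps)])
    while t[-1] < duration:
        extra = rng.uniform(1.0 / hi, 1.0 / lo, size=max(16, int(duration * hi) // 10))
        t = np.concatenate([t, t[-1] + np.cumsum(extra)])
    return t[: int(np.searchsorted(t, duration)) + 1]


def simulate_fall_trial(fall_type: str, params: FallSimParams | None = None,
                        seed=0, subject_id: str = "S0") -> RawRecording:
    """Simulate one fall trial of the given raw type.

    The recording runs quiet upright stance → (slowed, for faints) freefall →
    directional impact → lying still, with ≥5.5 s of signal on each side of
    the impact so a 10 s analysis clip can be centred on the fall.
    Annotations mark the phase boundaries (``phase:*``) and the fall instant
    (``fall:<merged label>``).
    """
    if fall_type not in RAW_FALL_TYPES:
        raise ValueError(
            f"unknown fall_type {fall_type!r}; valid types: {', '.join(RAW_FALL_TYPES)}"
        )
    params = params or FallSimParams()
    rng = _rng(seed)
    merged = MERGED_LABELS[fall_type]
    faint = fall_type.endswith("faint")

    stance = rng.uniform(*params.stance_duration)
    freefall = rng.uniform(*params.freefall_duration)
    if faint:
        freefall *= params.faint_descent_scale
    impact = rng.uniform(*params.impact_duration)
    lying = rng.uniform(*params.lying_duration)

    # guarantee a full clip window around the impact
    lead = max(0.0, 5.5 - (stance + freefall))
    t_ff = lead + stance
    t_imp = t_ff + freefall
    t_imp_end = t_imp + impact
    total = t_imp_end + max(lying, 5.5)

    t = _variable_timestamps(rng, total, params.rate_band)
    n = len(t)

    tilt = _random_tilt(rng, params.tilt_sd_deg)
    up = tilt @ _UP
    lie = tilt @ LYING_DIRECTION[merged]

    # gravity direction: upright until freefall starts, then rotate into the
    # lying orientation, completing as the impact ends
    frac = np.clip((t - t_ff) / (t_imp_end - t_ff), 0.0, 1.0)
    direction = _slerp(up, lie, frac)

    # specific-force magnitude profile
    mag = np.full(n, G)
    ff = (t >= t_ff) & (t < t_imp)
    m_min = rng.uniform(0.5, 1.5)
    s = (t[ff] - t_ff) / freefall
    mag[ff] = G + (m_min - G) * 0.5 * (1 - np.cos(np.pi * s))  # eases 9.8 -> m_min
    imp = (t >= t_imp) & (t < t_imp_end)
    peak = rng.uniform(*params.impact_peak)
    mag[imp] = peak

    samples = mag[:, None] * direction
    samples += rng.normal(0.0, params.sensor_noise_sd, size=(n, 3))
    if not faint:
        # pre-impact flailing: extra movement noise while losing balance
        flail = (t >= t_ff - 0.5) & (t < t_imp)
        samples[flail] += rng.normal(0.0, params.flail_sd, size=(int(flail.sum()), 3))

    annotations = [
        (float(t_ff), "phase:freefall"),
        (float(t_imp), "phase:impact"),
        (float(t_imp_end), "phase:lying"),
        (float(0.5 * (t_imp + t_imp_end)), f"fall:{merged}"),
    ]
    return RawRecording(t, samples, subject_id=subject_id, annotations=annotations)


def _wear_schedule(rng: np.random.Generator, duration: float, walk_fraction: float):
    """Alternating quiet/walk segments: list of (t_start, t_end, kind, orientation)."""
    # orientation = body axis currently pointing up, in sensor coordinates
    postures = [_UP,
                np.array([0.0, 0.0, -1.0]),  # supine
                np.array([0.0, -1.0, 0.0]),  # left side
                np.array([0.0, 1.0, 0.0])]   # right side
    probs = np.array([0.6, 0.15, 0.125, 0.125])
    segments = []
    t = 0.0
    while t < duration:
        quiet = rng.uniform(300.0, 1800.0)
        ori = postures[rng.choice(4, p=probs)]
        segments.append((t, min(t + quiet, duration), "quiet", ori))
        t += quiet
        if t >= duration or walk_fraction <= 0:
            continue
        walk = quiet * walk_fraction / (1.0 - walk_fraction) * rng.uniform(0.7, 1.3)
        walk = min(max(walk, 30.0), 600.0)
        segments.append((t, min(t + walk, duration), "walk", _UP))
        t += walk
    return segments


def simulate_wear_session(duration_hours: float,
                          params: ActivitySimParams | None = None,
                          seed=0, subject_id: str = "S0") -> RawRecording:
    """Simulate a daily-wear stream of quiet postures, walking bouts and jolts.

    Jolts are short additive spikes with neither a freefall dip nor a lasting
    orientation change — the high-jerk non-fall events a detector must reject.
    Each jolt time is annotated ``jolt``.
    """
    if duration_hours <= 0:
        raise ValueError("duration_hours must be positive")
    params = params or ActivitySimParams()
    rng = _rng(seed)
    duration = duration_hours * 3600.0

    t = _variable_timestamps(rng, duration, params.rate_band)
    n = len(t)
    samples = rng.normal(0.0, params.sensor_noise_sd, size=(n, 3))

    segments = _wear_schedule(rng, duration, params.walk_fraction)

    # gravity track with ~1.5 s smoothed posture transitions; some transitions
    # end with an impact-like bump (dropping onto a chair or bed), so mined
    # high-jerk negatives include events that genuinely resemble falls
    direction = np.empty((n, 3))
    prev_ori = segments[0][3]
    for t0, t1, kind, ori in segments:
        i0 = int(np.searchsorted(t, t0))
        i1 = n if t1 >= duration else int(np.searchsorted(t, t1))
        if i1 <= i0:
            prev_ori = ori
            continue
        seg_t = t[i0:i1]
        frac = np.clip((seg_t - t0) / 1.5, 0.0, 1.0)
        direction[i0:i1] = _slerp(prev_ori, ori, frac)
        if float(prev_ori @ ori) < 0.999:  # a real posture change
            trans = frac < 1.0
            samples[i0:i1][trans] += rng.normal(0.0, 1.0,
                                                size=(int(trans.sum()), 3))
            if rng.random() < 0.5:  # hard landing at the end of the transition
                amp = rng.uniform(8.0, 22.0)
                sigma = rng.uniform(0.04, 0.08)
                bump = amp * np.exp(-0.5 * ((seg_t - (t0 + 1.5)) / sigma) ** 2)
                samples[i0:i1] += bump[:, None] * ori[None, :]
        if kind == "walk":
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(1.5, 3.0)
            w = 2 * np.pi * params.walk_frequency
            rel = seg_t - t0
            samples[i0:i1, 0] += amp * np.sin(w * rel + phase)
            samples[i0:i1, 1] += 0.8 * amp * np.sin(0.5 * w * rel + phase)
            samples[i0:i1, 2] += 0.3 * amp * np.sin(w * rel + 2 * phase)
            samples[i0:i1] += rng.normal(0.0, 0.5, size=(i1 - i0, 3))
        prev_ori = ori
    samples += G * direction

    # jolts: Poisson-count additive spikes, annotated as ground truth
    annotations: list[tuple[float, str]] = []
    n_jolts = rng.poisson(params.jolt_rate * duration_hours)
    jolt_times = np.sort(rng.uniform(2.0, duration - 2.0, size=n_jolts))
    for tj in jolt_times:
        dirn = rng.normal(size=3)
        dirn /= np.linalg.norm(dirn)
        amp = rng.uniform(12.0, 30.0)
        sigma = rng.uniform(0.03, 0.06)
        i0, i1 = np.searchsorted(t, [tj - 5 * sigma, tj + 5 * sigma + 0.15])
        bump = amp * np.exp(-0.5 * ((t[i0:i1] - tj) / sigma) ** 2)
        if rng.random() < 0.4:  # double-contact jolt
            bump += 0.6 * amp * np.exp(-0.5 * ((t[i0:i1] - tj - 0.1) / sigma) ** 2)
        samples[i0:i1] += bump[:, None] * dirn[None, :]
        annotations.append((float(tj), "jolt"))

    return RawRecording(t, samples, subject_id=subject_id, annotations=annotations)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def generate_study(n_subjects: int, wear_hours_per_subject: float = 0.0,
                   fall_params: FallSimParams | None = None,
                   activity_params: ActivitySimParams | None = None,
                   seed=0, n_wear_subjects: int | None = None) -> StudyBundle:
    """Generate a full simulated study.

    Per subject: 3 trials of each of the 6 raw fall types (18 recordings),
    with active/faint lateral variants merged into the 4 reported classes.
    The first ``n_wear_subjects`` (default ``min(9, n_subjects)``) also get a
    daily-wear stream of ``wear_hours_per_subject`` hours; pass 0 wear hours
    for a falls-only study.  Identical arguments and seed reproduce the
    bundle bit for bit.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if n_wear_subjects is None:
        n_wear_subjects = min(9, n_subjects)
    root = np.random.SeedSequence(seed)
    fall_ss, wear_ss = root.spawn(2)

    falls: list[FallTrial] = []
    trial_seeds = iter(fall_ss.spawn(n_subjects * len(RAW_FALL_TYPES) * 3))
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        for raw_type in RAW_FALL_TYPES:
            for _ in range(3):
                rec = simulate_fall_trial(
                    raw_type, fall_params, seed=_child_seed(next(trial_seeds)),
                    subject_id=sid)
                falls.append(FallTrial(rec, raw_type, MERGED_LABELS[raw_type], sid))

    wear: list[RawRecording] = []
    if wear_hours_per_subject > 0:
        for i, ss in enumerate(wear_ss.spawn(n_wear_subjects)):
            wear.append(simulate_wear_session(
                wear_hours_per_subject, activity_params,
                seed=_child_seed(ss), subject_id=f"S{i + 1:02d}"))
    return StudyBundle(falls=falls, wear=wear)


def quiet_lying_params(**overrides) -> ActivitySimParams:
    """Activity parameters for a motionless lying-only control stream."""
    base = ActivitySimParams(walk_fraction=0.0, jolt_rate=0.0)
    return replace(base, **overrides)
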