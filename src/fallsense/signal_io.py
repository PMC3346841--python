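"""Recording I/O, 20 Hz resampling and 10-second clip extraction.

Recordings are exchanged as plain CSV with a ``t,x,y,z`` header (seconds and
m/s²), one file per recording, with ground-truth marks in an optional
``t,label`` sidecar.  Analysis runs on 10 s / 200-sample clips cut from a
uniform 20 Hz grid obtained by per-axis linear interpolation of the phone's
variable-rate stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import RawRecording

RATE = 20.0  # Hz, analysis grid
CLIP_SECONDS = 10.0
CLIP_SAMPLES = 200
_DT = 1.0 / RATE


@dataclass
class UniformClip:
    """A 10 s, 200-sample, 20 Hz tri-axial window."""

    samples: np.ndarray  # (200, 3)
    center_time: float
    label: str | None = None
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (CLIP_SAMPLES, 3):
            raise ValueError(f"clip must have shape ({CLIP_SAMPLES}, 3)")


def read_recording(path: str | Path, subject_id: str = "S0") -> RawRecording:
    """Read a ``t,x,y,z`` CSV into a RawRecording.

    Rejects files with missing columns, non-numeric cells, fewer than two
    rows, or non-increasing timestamps.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap with the path
        raise ValueError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in ("t", "x", "y", "z") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if len(df) < 2:
        raise ValueError(f"{path}: need at least 2 rows, got {len(df)}")
    arr = df[["t", "x", "y", "z"]].apply(pd.to_numeric, errors="coerce").to_numpy()
    if np.isnan(arr).any():
        raise ValueError(f"{path}: non-numeric cell(s) in t,x,y,z")
    if not np.all(np.diff(arr[:, 0]) > 0):
        raise ValueError(f"{path}: timestamps must be strictly increasing")
    ann_path = annotation_path(path)
    annotations = read_annotations(ann_path) if Path(ann_path).exists() else []
    return RawRecording(arr[:, 0], arr[:, 1:], subject_id=subject_id,
                        annotations=annotations)


def write_recording(rec: RawRecording, path: str | Path,
                    write_annotations: bool = True) -> None:
    """Write a recording as ``t,x,y,z`` CSV (plus a label sidecar if annotated)."""
    df = pd.DataFrame({"t": rec.timestamps, "x": rec.samples[:, 0],
                       "y": rec.samples[:, 1], "z": rec.samples[:, 2]})
    df.to_csv(path, index=False)
    if write_annotations and rec.annotations:
        pd.DataFrame(rec.annotations, columns=["t", "label"]).to_csv(
            annotation_path(path), index=False)


def annotation_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(".annotations.csv")


def read_annotations(path: str | Path) -> list[tuple[float, str]]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [(float(t), str(lab)) for t, lab in zip(df["t"], df["label"])]


def resample_uniform(rec: RawRecording, rate: float = RATE) -> RawRecording:
    """Linearly interpolate each axis onto an exact 1/rate grid.

    The grid is anchored at the first timestamp and spans the recorded
    interval only (no extrapolation).  A recording already on the grid is
    returned unchanged up to floating tolerance.
    """
    if len(rec) < 2:
        raise ValueError("resampling needs at least 2 samples")
    t0, t1 = rec.timestamps[0], rec.timestamps[-1]
    n_out = int(np.floor((t1 - t0) * rate + 1e-9)) + 1
    grid = t0 + np.arange(n_out) / rate
    out = np.column_stack(
        [np.interp(grid, rec.timestamps, rec.samples[:, j]) for j in range(3)])
    return RawRecording(grid, out, subject_id=rec.subject_id,
                        annotations=list(rec.annotations))


def is_uniform(rec: RawRecording, rate: float = RATE, tol: float = 1e-6) -> bool:
    gaps = np.diff(rec.timestamps)
    return bool(gaps.size > 0 and np.all(np.abs(gaps - 1.0 / rate) < tol))


def extract_clip(rec: RawRecording, center_time: float,
                 label: str | None = None) -> UniformClip:
    """Cut the 200-sample window centred on the grid point nearest center_time.

    The window is half-open, [start, start + 10 s).  Near a recording edge it
    is shifted minimally to stay inside the data — never padded, since padded
    zeros would corrupt moment and spectral features.
    """
    if not is_uniform(rec, RATE):
        raise ValueError("extract_clip requires a uniform 20 Hz recording")
    n = len(rec)
    if n < CLIP_SAMPLES:
        raise ValueError(
            f"recording shorter than {CLIP_SECONDS:.0f} s ({n} samples < {CLIP_SAMPLES})")
    t0 = rec.timestamps[0]
    center_idx = int(round((center_time - t0) * RATE))
    start = int(np.clip(center_idx - CLIP_SAMPLES // 2, 0, n - CLIP_SAMPLES))
    window = rec.samples[start:start + CLIP_SAMPLES].copy()
    actual_center = float(t0 + (start + CLIP_SAMPLES // 2) * _DT)
    return UniformClip(window, center_time=actual_center, label=label,
                       subject_id=rec.subject_id)
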