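"""End-to-end experiments: fall-type classification and fall detection.

Two tasks mirror the study design: (i) classify the 4 merged fall classes
from simulated fall clips, and (ii) detect falls against the hard negative
class of high-jerk "fall-like" events mined from daily-wear streams at one
per recorded hour.  Each task evaluates any set of classifier specs under
pooled stratified 10-fold and leave-one-subject-out crossvalidation and
writes plain CSV/JSON artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import event_extraction, signal_io
from .classification import ClassifierSpec, EvalResult, evaluate, grid_search
from .features import FEATURE_NAMES, extract_features
from .synthetic_data import (ActivitySimParams, FallSimParams, StudyBundle,
                             generate_study)

DEFAULT_SPECS = tuple(ClassifierSpec(family=f) for f in
                      ("svm-rbf", "smlr", "naive-bayes", "decision-tree", "knn"))


@dataclass
class ExperimentConfig:
    task: str  # "classification" or "detection"
    n_subjects: int = 15
    n_wear_subjects: int = 9
    wear_hours: float = 24.0
    specs: tuple[ClassifierSpec, ...] = DEFAULT_SPECS
    schemes: tuple[str, ...] = ("kfold-10", "subject-wise")
    seed: int = 0
    grid: bool = False  # grid-search hyperparameters instead of the defaults
    fall_params: FallSimParams | None = None
    activity_params: ActivitySimParams | None = None
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.task not in ("classification", "detection"):
            raise ValueError("task must be 'classification' or 'detection'")
        if self.task == "detection" and self.wear_hours < 1.0:
            raise ValueError("detection requires wear_hours >= 1 per wear subject")


def _task_seed(master: int, task: str) -> int:
    # fixed per-task offsets so either experiment reproduces independently
    offset = {"classification": 0, "detection": 1}[task]
    return int(np.random.SeedSequence([master, offset]).generate_state(1)[0]
               % (2**31))


def fall_feature_table(study: StudyBundle) -> pd.DataFrame:
    """One 178-feature row per fall trial, clipped at the annotated instant."""
    rows, labels, subjects = [], [], []
    for trial in study.falls:
        uniform = signal_io.resample_uniform(trial.recording)
        t_fall = next(t for t, lab in trial.recording.annotations
                      if lab.startswith("fall:"))
        clip = signal_io.extract_clip(uniform, t_fall, label=trial.label)
        rows.append(extract_features(clip).values)
        labels.append(trial.label)
        subjects.append(trial.subject_id)
    df = pd.DataFrame(np.vstack(rows), columns=FEATURE_NAMES)
    df["label"] = labels
    df["subject_id"] = subjects
    return df


def negative_feature_table(wear: list) -> pd.DataFrame:
    """One feature row per mined fall-like event, labelled ``non-fall``."""
    rows, subjects = [], []
    for rec in wear:
        for session in event_extraction.split_sessions(rec):
            if session.duration < 3600.0:
                continue
            uniform = signal_io.resample_uniform(session)
            for cand in event_extraction.hourly_candidates(uniform):
                clip = signal_io.extract_clip(uniform, cand.center_time,
                                              label="non-fall")
                rows.append(extract_features(clip).values)
                subjects.append(rec.subject_id)
    if not rows:
        raise ValueError("no fall-like events mined; increase wear_hours "
                         "(at least one whole recorded hour per subject)")
    df = pd.DataFrame(np.vstack(rows), columns=FEATURE_NAMES)
    df["label"] = "non-fall"
    df["subject_id"] = subjects
    return df


def _evaluate_all(cfg: ExperimentConfig, table: pd.DataFrame,
                  seed: int) -> dict[tuple[str, str], EvalResult]:
    X = table[FEATURE_NAMES].to_numpy()
    y = table["label"].to_numpy()
    subjects = table["subject_id"].to_numpy()
    results: dict[tuple[str, str], EvalResult] = {}
    for spec in cfg.specs:
        if cfg.grid and spec.family in ("svm-rbf", "smlr", "knn"):
            spec = grid_search(spec.family, X, y, seed=seed)
        for scheme in cfg.schemes:
            results[(spec.family, scheme)] = evaluate(
                spec, X, y, subjects=subjects, scheme=scheme, seed=seed)
    return results


def run_classification_experiment(cfg: ExperimentConfig):
    """Simulate the study, featurize every fall clip, evaluate all classifiers."""
    if cfg.task != "classification":
        raise ValueError("cfg.task must be 'classification'")
    seed = _task_seed(cfg.seed, "classification")
    study = generate_study(cfg.n_subjects, 0.0, cfg.fall_params,
                           cfg.activity_params, seed=seed)
    table = fall_feature_table(study)
    results = _evaluate_all(cfg, table, seed)
    if cfg.out_dir is not None:
        _write_outputs(cfg, table, results, "classification")
    return table, results


def run_detection_experiment(cfg: ExperimentConfig):
    """Falls (positive) versus mined fall-like events (negative), two classes."""
    if cfg.task != "detection":
        raise ValueError("cfg.task must be 'detection'")
    seed = _task_seed(cfg.seed, "detection")
    study = generate_study(cfg.n_subjects, cfg.wear_hours, cfg.fall_params,
                           cfg.activity_params, seed=seed,
                           n_wear_subjects=cfg.n_wear_subjects)
    pos = fall_feature_table(study)
    pos["label"] = "fall"
    neg = negative_feature_table(study.wear)
    table = pd.concat([pos, neg], ignore_index=True)
    results = _evaluate_all(cfg, table, seed)
    if cfg.out_dir is not None:
        _write_outputs(cfg, table, results, "detection")
    return table, results


def report(results: dict) -> pd.DataFrame:
    """Tabulate accuracy per classifier × (task, scheme); flag the best per column.

    ``results`` maps (task, family, scheme) or (family, scheme) keys to
    EvalResults.  The returned frame has one row per classifier family and
    one accuracy column per task/scheme, plus boolean ``best_*`` columns
    marking every classifier tied for the column maximum.
    """
    if not results:
        raise ValueError("no results to report")
    records = {}
    for key, res in results.items():
        if len(key) == 3:
            task, family, scheme = key
            col = f"{task}/{scheme}"
        else:
            family, scheme = key
            col = scheme
        records.setdefault(family, {})[col] = res.accuracy
    df = pd.DataFrame.from_dict(records, orient="index").sort_index()
    for col in list(df.columns):
        df[f"best_{col}"] = np.isclose(df[col], df[col].max())
    df.index.name = "classifier"
    return df


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    payload = {"columns": list(df.columns), "index": list(df.index),
               "data": df.to_numpy().tolist()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_report(path: str | Path) -> pd.DataFrame:
    payload = json.loads(Path(path).read_text())
    df = pd.DataFrame(payload["data"], index=payload["index"],
                      columns=payload["columns"])
    df.index.name = "classifier"
    return df


def _write_outputs(cfg: ExperimentConfig, table: pd.DataFrame,
                   results: dict, task: str) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / f"{task}_features.csv", index=False)
    summary = {f"{family}|{scheme}": res.to_dict()
               for (family, scheme), res in results.items()}
    (out / f"{task}_results.json").write_text(json.dumps(summary, indent=1))
    write_report(report(results), out / f"{task}_report.json")
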