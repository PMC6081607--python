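"""File schemas and validated readers/writers.

All tables are comma-separated UTF-8 with a header row and "." decimals.
Coordinates are normalized [0, 1], origin top-left.

Schemas
-------
gaze.csv       subject_id, trial, t_ms, left_x, left_y, right_x, right_y, valid
codes.csv      subject_id, trial, frame, rater, code
trials.json    {subject_id: [{trial, novel_side, delay_condition,
                              familiarization_ms, test_phase_ms}, ...]}
cognition.csv  subject_id, <component columns>
truth.json     {subject_id: {ability, mean_np, trial_true_np, novel_side}}
norms.yaml     {component: {mean, sd, reverse?}}
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic_data import GroundTruth, SubjectDataset
from .types import CODES, SIDES


class SchemaError(ValueError):
    """A file violates its declared schema; the message names the row."""


GAZE_SCHEMA = ["subject_id", "trial", "t_ms", "left_x", "left_y",
               "right_x", "right_y", "valid"]
CODES_SCHEMA = ["subject_id", "trial", "frame", "rater", "code"]


def _check_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    if list(df.columns) != expected:
        raise SchemaError(f"{path}: columns {list(df.columns)} != {expected}")


def read_gaze(path) -> pd.DataFrame:
    """Read and validate a gaze-sample table."""
    df = pd.read_csv(path)
    _check_columns(df, GAZE_SCHEMA, path)
    coords = df[["left_x", "left_y", "right_x", "right_y"]].to_numpy(float)
    with np.errstate(invalid="ignore"):
        bad = np.flatnonzero(((coords < 0) | (coords > 1)).any(axis=1))
    if bad.size:
        raise SchemaError(f"{path}: coordinate outside [0,1] at row {bad[0] + 2}")
    df["valid"] = df["valid"].astype(bool)
    for (subj, trial), grp in df.groupby(["subject_id", "trial"]):
        t = grp["t_ms"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise SchemaError(
                f"{path}: non-increasing t_ms in subject {subj} trial {trial}")
    return df


def read_codes(path) -> pd.DataFrame:
    """Read and validate a frame-code table."""
    df = pd.read_csv(path)
    _check_columns(df, CODES_SCHEMA, path)
    bad = ~df["code"].isin(CODES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{path}: unknown code {df['code'].iloc[row]!r} at row {row + 2}")
    dup = df.duplicated(["subject_id", "trial", "frame", "rater"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise SchemaError(f"{path}: duplicate (trial, frame, rater) at row {row + 2}")
    return df


def read_trials(path) -> dict[str, pd.DataFrame]:
    """Read per-subject trial metadata from trials.json."""
    with open(path) as fh:
        raw = json.load(fh)
    out: dict[str, pd.DataFrame] = {}
    for subject, rows in raw.items():
        df = pd.DataFrame(rows)
        if not df["novel_side"].isin(SIDES).all():
            raise SchemaError(f"{path}: bad novel_side for subject {subject}")
        out[subject] = df
    return out


def read_cognition(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise SchemaError(f"{path}: missing subject_id column")
    return df


def read_norms(path) -> dict[str, dict]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for comp, spec in raw.items():
        if "mean" not in spec or "sd" not in spec:
            raise SchemaError(f"{path}: component {comp} needs mean and sd")
    return raw


def write_cohort(datasets: list[SubjectDataset], truth: GroundTruth | None,
                 outdir) -> dict[str, Path]:
    """Write a simulated cohort to the five on-disk artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    gaze = pd.concat(
        [d.gaze.assign(subject_id=d.subject_id) for d in datasets],
        ignore_index=True)[GAZE_SCHEMA]
    paths["gaze"] = outdir / "gaze.csv"
    gaze.to_csv(paths["gaze"], index=False, float_format="%.6f")

    codes = pd.concat(
        [d.codes.assign(subject_id=d.subject_id) for d in datasets],
        ignore_index=True)[CODES_SCHEMA]
    paths["codes"] = outdir / "codes.csv"
    codes.to_csv(paths["codes"], index=False)

    trials = {d.subject_id: d.trials.to_dict(orient="records") for d in datasets}
    paths["trials"] = outdir / "trials.json"
    paths["trials"].write_text(json.dumps(trials, indent=1))

    cog = pd.DataFrame([{"subject_id": d.subject_id, **d.cognition}
                        for d in datasets])
    paths["cognition"] = outdir / "cognition.csv"
    cog.to_csv(paths["cognition"], index=False, float_format="%.6f")

    if truth is not None:
        payload = {}
        for i, d in enumerate(datasets):
            payload[d.subject_id] = {
                "ability": float(truth.ability[i]),
                "mean_np": float(truth.subject_mean_np[i]),
                "trial_true_np": [float(v) for v in truth.trial_true_np[i]],
                "novel_side": list(truth.novel_side[i]),
            }
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths


def load_cohort(indir) -> tuple[pd.DataFrame, pd.DataFrame,
                                dict[str, pd.DataFrame], pd.DataFrame]:
    """Read back (gaze, codes, trials, cognition) from a cohort directory."""
    indir = Path(indir)
    return (read_gaze(indir / "gaze.csv"),
            read_codes(indir / "codes.csv"),
            read_trials(indir / "trials.json"),
            read_cognition(indir / "cognition.csv"))
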