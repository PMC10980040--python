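"""File formats and validated dataset loading.

Tab-separated tables with fixed schemas (times in minutes, one row per
frame, '.' decimal, UTF-8):

- subjects.tsv: subject_id, group, age, sex, f_P_true*, f_P_measured, scan_date
  (* optional; present for synthetic cohorts)
- tacs.tsv: subject_id, region, frame_start_min, frame_dur_min, conc
- blood.tsv: subject_id, time_min, parent_plasma, whole_plasma

Reading validates schemas and reports malformed rows with their line
numbers; every artifact directory gets a manifest (config hash, seed,
package version) sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import FrameSchedule, InputFunction, TissueTAC

__all__ = ["Dataset", "write_cohort", "read_dataset", "write_manifest"]

SUBJECT_COLS = ["subject_id", "group", "age", "sex", "f_P_measured", "scan_date"]
TAC_COLS = ["subject_id", "region", "frame_start_min", "frame_dur_min", "conc"]
BLOOD_COLS = ["subject_id", "time_min", "parent_plasma", "whole_plasma"]


@dataclass
class Dataset:
    """In-memory dataset with the same surface the model fitters expect."""

    subjects: pd.DataFrame
    inputs: dict  # subject_id -> InputFunction
    tacs: list  # TissueTAC

    @property
    def schedule(self) -> FrameSchedule:
        return self.tacs[0].schedule


def _require_columns(df: pd.DataFrame, cols: list, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def _check_numeric(df: pd.DataFrame, cols: list, path) -> None:
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[vals.isna() & df[c].notna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise ValueError(f"{path}: non-numeric value in column {c!r} at line {bad[0] + 2}")
        if df[c].isna().any():
            raise ValueError(f"{path}: missing value in column {c!r}")


def write_cohort(cohort, outdir, seed: int | None = None) -> dict:
    """Write subjects/tacs/blood TSVs (+ manifest) for a synthetic cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects = cohort.subjects
    tacs = cohort.tac_table()
    blood = cohort.blood_table()
    subjects.to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    tacs.to_csv(outdir / "tacs.tsv", sep="\t", index=False)
    blood.to_csv(outdir / "blood.tsv", sep="\t", index=False)
    cfg = {k: _jsonable(v) for k, v in vars(cohort.config).items()}
    manifest = write_manifest(outdir, config=cfg, seed=seed if seed is not None else cohort.config.seed)
    return manifest


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def write_manifest(outdir, config: dict | None = None, seed: int | None = None, **extra) -> dict:
    from . import __version__

    payload = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "config_hash": hashlib.sha256(payload.encode()).hexdigest()[:16],
        "config": config,
        "seed": seed,
        "petmba_version": __version__,
        **extra,
    }
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def read_dataset(subjects_path, tacs_path, blood_path) -> Dataset:
    """Read and validate the three TSVs into a Dataset.

    Errors name the file, column and (1-based) line of the first offending
    row: missing columns, non-numeric cells, duplicate subject x region x
    frame rows, non-increasing blood sample times.
    """
    subjects = pd.read_csv(subjects_path, sep="\t")
    _require_columns(subjects, SUBJECT_COLS, subjects_path)
    _check_numeric(subjects, ["age", "f_P_measured", "scan_date"], subjects_path)
    if subjects["subject_id"].duplicated().any():
        dup = subjects["subject_id"][subjects["subject_id"].duplicated()].iloc[0]
        raise ValueError(f"{subjects_path}: duplicate subject_id {dup!r}")

    tacs_df = pd.read_csv(tacs_path, sep="\t")
    _require_columns(tacs_df, TAC_COLS, tacs_path)
    _check_numeric(tacs_df, ["frame_start_min", "frame_dur_min", "conc"], tacs_path)
    dups = tacs_df.duplicated(subset=["subject_id", "region", "frame_start_min"])
    if dups.any():
        i = int(np.flatnonzero(dups)[0])
        raise ValueError(
            f"{tacs_path}: duplicate subject x region x frame at line {i + 2}"
        )

    blood = pd.read_csv(blood_path, sep="\t")
    _require_columns(blood, BLOOD_COLS, blood_path)
    _check_numeric(blood, ["time_min", "parent_plasma", "whole_plasma"], blood_path)

    inputs = {}
    for sid, sub in blood.groupby("subject_id", sort=False):
        t = sub["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            i = int(sub.index[np.flatnonzero(np.diff(t) <= 0)[0] + 1])
            raise ValueError(f"{blood_path}: time not increasing at line {i + 2}")
        inputs[sid] = InputFunction(
            time=t,
            c_plasma_parent=sub["parent_plasma"].to_numpy(dtype=float),
            c_wholeplasma=sub["whole_plasma"].to_numpy(dtype=float),
        )

    tacs = []
    for (sid, region), sub in tacs_df.groupby(["subject_id", "region"], sort=False):
        sub = sub.sort_values("frame_start_min")
        sched = FrameSchedule(
            frame_start=sub["frame_start_min"].to_numpy(dtype=float),
            frame_duration=sub["frame_dur_min"].to_numpy(dtype=float),
        )
        tacs.append(TissueTAC(sid, region, sched, sub["conc"].to_numpy(dtype=float)))
        if sid not in inputs:
            raise ValueError(f"{tacs_path}: subject {sid!r} has no blood data")
    return Dataset(subjects=subjects, inputs=inputs, tacs=tacs)


def write_draws(draws, path) -> None:
    """Long-format gzip-compressed draws table (chain, draw, parameter, value)."""
    draws.to_tidy().to_csv(path, sep="\t", index=False, compression="gzip")


def read_draws(path):
    from .draws import PosteriorDraws

    return PosteriorDraws.from_tidy(pd.read_csv(path, sep="\t", compression="gzip"))
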