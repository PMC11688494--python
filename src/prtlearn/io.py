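"""Readers, writers and run manifests for the pipeline's plain-text formats.

Trial tables are UTF-8 CSV with the fixed header
``subject_id,session,block,trial,stimulus,action,correct,reward,points,rt``
(missing RT is an empty field).  Parameter tables, priors, comparisons and
reports are CSV/JSON.  Cohort and task configuration round-trips through
YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .task import CohortSpec, TaskConfig, TRIAL_COLUMNS

__all__ = [
    "read_trials",
    "write_trials",
    "read_params_table",
    "write_params_table",
    "load_task_config",
    "load_cohort_spec",
    "dump_config",
    "write_manifest",
    "TrialValidationError",
]


class TrialValidationError(ValueError):
    """A trial table violates its schema; the message names offending rows."""


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialValidationError(f"missing columns: {missing}")
    if len(trials) == 0:
        raise TrialValidationError("trial table is empty")
    problems = []
    reward = pd.to_numeric(trials["reward"], errors="coerce")
    bad = trials.index[~reward.isin([0, 1])]
    if len(bad):
        problems.append(f"non-binary reward at rows {list(bad[:5])}")
    correct = trials["correct"]
    if correct.dtype != bool:
        correct = correct.astype(str).str.lower().isin(["true", "1"])
    bad = trials.index[(reward == 1) & (~correct)]
    if len(bad):
        problems.append(f"reward delivered on incorrect trial at rows {list(bad[:5])}")
    bad = trials.index[~trials["stimulus"].isin(["rich", "lean"])]
    if len(bad):
        problems.append(f"stimulus not rich/lean at rows {list(bad[:5])}")
    if problems:
        raise TrialValidationError("; ".join(problems))
    out = trials.copy()
    out["correct"] = correct
    out["reward"] = reward.astype(int)
    out["points"] = pd.to_numeric(out["points"]).astype(int)
    out["rt"] = pd.to_numeric(out["rt"], errors="coerce")
    return out


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and schema-validate a trial CSV."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise TrialValidationError(f"{path} is empty")
    trials = pd.read_csv(path)
    if len(trials) == 0:
        raise TrialValidationError(f"{path} has a header but no trials")
    return validate_trials(trials)


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    # fixed RT precision (µs) so write -> read -> write is byte-stable
    trials = trials[TRIAL_COLUMNS]
    trials.to_csv(path, index=False, float_format="%.3f")


def read_params_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_params_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def _spec_from_mapping(cls, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    kwargs = dict(data)
    for key in ("sessions", "mouth_lengths_mm"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_task_config(path: str | Path) -> TaskConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _spec_from_mapping(TaskConfig, data.get("task", data))
    cfg.validate()
    return cfg


def load_cohort_spec(path: str | Path) -> CohortSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    spec = _spec_from_mapping(CohortSpec, data.get("cohort", data))
    spec.validate()
    return spec


def dump_config(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(dataclasses.asdict(obj)), fh, sort_keys=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_manifest(path: str | Path, **entries) -> None:
    """Record what a run did: config, seeds, package version."""
    from . import __version__

    manifest = {"prtlearn_version": __version__}
    for key, value in entries.items():
        if dataclasses.is_dataclass(value) and not isinstance(value, type):
            value = dataclasses.asdict(value)
        manifest[key] = _jsonable(value)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
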