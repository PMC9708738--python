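"""Trial-log file formats and run manifests.

All on-disk formats are plain CSV (comma delimiter, ``.`` decimal, UTF-8)
with a ``#``-prefixed metadata header of ``key=value`` lines recording
units, seeds, schema version and the run's manifest hash.  Trial indices
are 0-based; the only units are centimeters (space) and seconds (time).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .schedules import StimulusSchedule

__all__ = [
    "SCHEMA_VERSION",
    "REQUIRED_COLUMNS",
    "write_trial_log",
    "read_trial_log",
    "validate_trial_log",
    "write_schedule_csv",
    "read_schedule_csv",
    "config_hash",
    "write_manifest",
    "read_manifest",
]

SCHEMA_VERSION = "1"

#: Required columns per task, beyond the common identity columns.
_COMMON = ("participant", "group", "condition", "task", "trial_index")
REQUIRED_COLUMNS = {
    "reproduction": _COMMON + ("stimulus", "response"),
    "discrimination": _COMMON + (
        "standard", "comparison", "comparison_position", "choice",
        "comparison_judged_longer",
    ),
    "pointing": _COMMON + ("x_s", "y_s", "x_r", "y_r"),
    "rhythm": _COMMON + ("interval",),
}


def _write_header(fh, metadata: dict) -> None:
    fh.write(f"# schema_version={SCHEMA_VERSION}\n")
    for k, v in metadata.items():
        if "\n" in str(v) or "=" in str(k):
            raise ValueError(f"metadata {k!r} not representable in header")
        fh.write(f"# {k}={v}\n")


def _read_header(path: Path) -> dict:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def write_trial_log(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a tidy trial log with a ``#`` metadata header."""
    path = Path(path)
    validate_trial_log(df)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        _write_header(fh, metadata or {})
        df.to_csv(fh, index=False)


def read_trial_log(path) -> tuple[pd.DataFrame, dict]:
    """Read a trial log; returns (frame, header metadata).  Round-trips
    :func:`write_trial_log` losslessly field-for-field."""
    path = Path(path)
    meta = _read_header(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    validate_trial_log(df, source=str(path))
    return df, meta


def validate_trial_log(df: pd.DataFrame, source: str = "<frame>") -> None:
    """Schema check with row/column-precise error messages."""
    if "task" not in df.columns:
        raise ValueError(f"{source}: missing column 'task'")
    for task, sub in df.groupby("task"):
        if task not in REQUIRED_COLUMNS:
            raise ValueError(f"{source}: unknown task {task!r}")
        missing = [c for c in REQUIRED_COLUMNS[task] if c not in df.columns]
        if missing:
            raise ValueError(f"{source}: task {task!r} missing column(s) {missing}")
        key = ["participant", "condition", "task", "trial_index"]
        dup = sub.duplicated(subset=key)
        if dup.any():
            row = sub.index[dup][0]
            raise ValueError(
                f"{source}: duplicate (participant, condition, task, trial_index) at row {row}"
            )
        bad_cond = ~sub["condition"].isin(["space", "time"])
        if bad_cond.any():
            row = sub.index[bad_cond][0]
            raise ValueError(f"{source}: invalid condition at row {row}")


def write_schedule_csv(schedule: StimulusSchedule, path) -> None:
    """Schedule export: ``trial_index, set_index, magnitude, nuisance`` with
    condition/task/units/seed in the metadata header."""
    path = Path(path)
    meta = {
        "condition": schedule.condition,
        "task": schedule.task,
        "units": schedule.units,
        "seed": schedule.seed,
        "levels": " ".join(repr(x) for x in schedule.levels),
    }
    with open(path, "w", encoding="utf-8", newline="") as fh:
        _write_header(fh, meta)
        fh.write("trial_index,set_index,magnitude,nuisance\n")
        for i, (set_index, mag) in enumerate(schedule.trials):
            nuis = "" if schedule.nuisance is None else repr(schedule.nuisance[i])
            fh.write(f"{i},{set_index},{mag!r},{nuis}\n")


def read_schedule_csv(path) -> StimulusSchedule:
    """Inverse of :func:`write_schedule_csv` (bit-exact round trip)."""
    path = Path(path)
    meta = _read_header(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for key in ("condition", "task", "units", "seed", "levels"):
        if key not in meta:
            raise ValueError(f"{path}: schedule header missing {key!r}")
    nuisance = None
    if df["nuisance"].notna().any():
        nuisance = tuple(float(x) for x in df["nuisance"])
    return StimulusSchedule(
        condition=meta["condition"],
        task=meta["task"],
        levels=tuple(float(x) for x in meta["levels"].split()),
        trials=tuple(
            (int(s), float(m)) for s, m in zip(df["set_index"], df["magnitude"])
        ),
        units=meta["units"],
        seed=int(meta["seed"]),
        nuisance=nuisance,
    )


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


def write_manifest(out_dir, config: dict, seed: int, extra: dict | None = None) -> dict:
    from . import __version__

    manifest = {
        "package_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "seed": int(seed),
        "config_hash": config_hash(config),
        **(extra or {}),
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return manifest


def read_manifest(out_dir) -> dict:
    path = Path(out_dir) / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.json in {out_dir}")
    return json.loads(path.read_text(encoding="utf-8"))
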