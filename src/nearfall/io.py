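"""File I/O: kinematics and cluster CSV, thresholds/results JSON, labels CSV.

Time series travel as plain CSV (SI units), thresholds and results as
JSON, configuration as YAML — all human-diffable and language-neutral.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError
from .kinematics import ClusterSeries, KinematicsSeries
from .thresholds import PersonalisedThresholds

_DT_RTOL = 1e-6

KINEMATICS_COLUMNS = ["t", "omega_y", "alpha_y"]
CLUSTER_COLUMNS = ["t"] + [
    f"s{i}_{ch}{ax}" for i in range(4) for ch in ("a", "w") for ax in "xyz"
]


def _check_uniform(t: np.ndarray, path: str) -> None:
    if len(t) < 2:
        raise ParseError(f"{path}: fewer than two samples")
    steps = np.diff(t)
    dt = steps[0]
    bad = np.nonzero(~np.isclose(steps, dt, rtol=_DT_RTOL, atol=1e-12))[0]
    if dt <= 0 or len(bad):
        row = int(bad[0]) + 2 if len(bad) else 1
        raise ParseError(
            f"{path}: non-uniform time grid at data row {row} "
            f"(spacing {steps[bad[0]] if len(bad) else dt:.9g} s vs {dt:.9g} s)"
        )


def read_kinematics_csv(path: str | Path) -> KinematicsSeries:
    """Read a kinematics CSV with columns t, omega_y, alpha_y (by name)."""
    path = str(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in KINEMATICS_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if frame[KINEMATICS_COLUMNS].isna().any().any():
        row = int(frame[KINEMATICS_COLUMNS].isna().any(axis=1).idxmax()) + 2
        raise ParseError(f"{path}: malformed/missing value at data row {row}")
    t = frame["t"].to_numpy(dtype=float)
    _check_uniform(t, path)
    omega = None
    alpha = None
    if all(f"omega_{ax}" in frame.columns for ax in "xyz"):
        omega = frame[[f"omega_{ax}" for ax in "xyz"]].to_numpy(dtype=float)
    if all(f"alpha_{ax}" in frame.columns for ax in "xyz"):
        alpha = frame[[f"alpha_{ax}" for ax in "xyz"]].to_numpy(dtype=float)
    return KinematicsSeries(
        t=t,
        omega_y=frame["omega_y"].to_numpy(dtype=float),
        alpha_y=frame["alpha_y"].to_numpy(dtype=float),
        omega=omega,
        alpha=alpha,
    )


def write_kinematics_csv(kin: KinematicsSeries, path: str | Path) -> None:
    data = {"t": kin.t, "omega_y": kin.omega_y, "alpha_y": kin.alpha_y}
    if kin.omega is not None:
        for j, ax in enumerate("xyz"):
            data[f"omega_{ax}"] = kin.omega[:, j]
    if kin.alpha is not None:
        for j, ax in enumerate("xyz"):
            data[f"alpha_{ax}"] = kin.alpha[:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def read_cluster_csv(path: str | Path) -> ClusterSeries:
    """Read a raw four-package cluster CSV (t, s0_ax..s3_wz)."""
    path = str(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in CLUSTER_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    t = frame["t"].to_numpy(dtype=float)
    _check_uniform(t, path)
    n = len(t)
    a = np.empty((n, 4, 3))
    w = np.empty((n, 4, 3))
    for i in range(4):
        for j, ax in enumerate("xyz"):
            a[:, i, j] = frame[f"s{i}_a{ax}"].to_numpy(dtype=float)
            w[:, i, j] = frame[f"s{i}_w{ax}"].to_numpy(dtype=float)
    return ClusterSeries(t=t, a=a, w=w)


def write_cluster_csv(series: ClusterSeries, path: str | Path) -> None:
    data = {"t": series.t}
    for i in range(4):
        for j, ax in enumerate("xyz"):
            data[f"s{i}_a{ax}"] = series.a[:, i, j]
            data[f"s{i}_w{ax}"] = series.w[:, i, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def write_thresholds_json(
    th: PersonalisedThresholds, path: str | Path, config_echo: Optional[dict] = None
) -> None:
    payload = {"thresholds": th.to_dict()}
    if config_echo is not None:
        payload["config"] = config_echo
    Path(path).write_text(json.dumps(payload, indent=2))


def read_thresholds_json(path: str | Path) -> PersonalisedThresholds:
    p = Path(path)
    if not p.exists():
        raise ParseError(f"thresholds file not found: {p}")
    try:
        payload = json.loads(p.read_text())
        return PersonalisedThresholds.from_dict(payload["thresholds"])
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise ParseError(f"{p}: not a thresholds file ({exc})") from exc


def write_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_labels_csv(labels: Sequence, path: str | Path) -> None:
    rows = []
    for i, lab in enumerate(labels):
        rows.append(
            {
                "trial": i,
                "task": lab.task,
                "perturbed": int(lab.perturbed),
                "type": lab.type or "",
                "onset": "" if lab.onset is None else lab.onset,
                "preceding": lab.preceding or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(str(path), keep_default_na=False)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if "perturbed" not in frame.columns:
        raise ParseError(f"{path}: missing 'perturbed' column")
    return frame
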