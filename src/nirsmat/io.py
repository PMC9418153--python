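"""File formats: recording CSV, feature-table CSV, model JSON, YAML config.

The recording format mirrors what the acquisition computer saves: a
comma-separated table of per-channel hemoglobin values, preceded by
``#key=value`` metadata lines (subject id, group, age, sampling rate and
a protocol digest).  Validation is strict and fail-fast: small-cohort
clinical data warrants loud failures over silent coercion.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import DiscriminantModel
from .features import FEATURE_NAMES, FeatureTable
from .protocol import MATProtocol
from .simulate import CHANNELS, GROUPS, Recording

_FLOAT_FMT = "%.17g"  # round-trip exact for float64


class IOError_(ValueError):
    """Raised for malformed files or schemas."""


RECORDING_COLUMNS = ["time_s"] + [
    f"{ch}_{kind}" for ch in CHANNELS for kind in ("hbo", "hhb")
]


def _protocol_digest(p: MATProtocol) -> str:
    return ",".join(
        repr(v)
        for v in (
            p.rest_duration,
            p.question_duration,
            p.countdown_duration,
            p.answer_duration,
            p.feedback_duration,
            p.n_cycles,
            p.recovery_duration,
        )
    )


def _protocol_from_digest(digest: str) -> MATProtocol:
    parts = digest.split(",")
    if len(parts) != 7:
        raise IOError_(f"malformed protocol digest {digest!r}")
    vals = [float(v) for v in parts]
    return MATProtocol(
        rest_duration=vals[0],
        question_duration=vals[1],
        countdown_duration=vals[2],
        answer_duration=vals[3],
        feedback_duration=vals[4],
        n_cycles=int(vals[5]),
        recovery_duration=vals[6],
    )


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write one recording as commented-header CSV."""
    path = Path(path)
    lines = [
        f"#subject_id={rec.subject_id}",
        f"#group={rec.group}",
        f"#age={'' if rec.age is None else repr(float(rec.age))}",
        f"#sampling_rate={rec.sampling_rate!r}",
        f"#protocol={_protocol_digest(rec.protocol)}",
    ]
    n = rec.n_samples
    cols = {"time_s": np.arange(n) / rec.sampling_rate}
    for ch in CHANNELS:
        cols[f"{ch}_hbo"] = rec.hbo[ch]
        cols[f"{ch}_hhb"] = rec.hhb[ch]
    df = pd.DataFrame(cols, columns=RECORDING_COLUMNS)
    with path.open("w", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_recording(path: str | Path) -> Recording:
    """Read a recording CSV, validating schema and time-base uniformity."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            if "=" not in line:
                raise IOError_(f"{path}:{lineno}: malformed metadata line")
            key, _, value = line[1:].strip().partition("=")
            meta[key] = value
    for key in ("subject_id", "group", "sampling_rate", "protocol"):
        if key not in meta:
            raise IOError_(f"{path}: missing metadata key {key!r}")
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise IOError_(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing column(s) {missing}")
    bad = df[RECORDING_COLUMNS].isna()
    if bad.any().any():
        rows = list(df.index[bad.any(axis=1)][:5] + 2 + len(meta))
        raise IOError_(f"{path}: non-numeric or missing values near lines {rows}")
    fs = float(meta["sampling_rate"])
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise IOError_(f"{path}: time_s must be strictly increasing")
        if np.max(np.abs(steps - 1.0 / fs)) > 1e-6 / fs:
            raise IOError_(
                f"{path}: non-uniform time step (expected {1.0 / fs:g} s)"
            )
    group = meta["group"].upper()
    if group not in GROUPS + ("UNKNOWN",):
        raise IOError_(f"{path}: unknown group string {meta['group']!r}")
    age = float(meta["age"]) if meta.get("age") else None
    return Recording(
        subject_id=meta["subject_id"],
        group=group,
        sampling_rate=fs,
        protocol=_protocol_from_digest(meta["protocol"]),
        hbo={ch: df[f"{ch}_hbo"].to_numpy(dtype=float) for ch in CHANNELS},
        hhb={ch: df[f"{ch}_hhb"].to_numpy(dtype=float) for ch in CHANNELS},
        age=age,
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Feature-table CSV: subject_id, group, age, then the 144 columns."""
    table.df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("subject_id", "group") if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing column(s) {missing}")
    if "age" not in df.columns:
        df["age"] = np.nan
    ordered = ["subject_id", "group", "age"] + list(FEATURE_NAMES)
    absent = [c for c in FEATURE_NAMES if c not in df.columns]
    if absent:
        raise IOError_(
            f"{path}: missing {len(absent)} feature column(s), e.g. {absent[0]!r}"
        )
    return FeatureTable(df[ordered])


def write_model(model: DiscriminantModel, path: str | Path) -> None:
    """Serialize a fitted discriminant as a flat JSON text file."""
    payload = {
        "kind": model.kind,
        "classes": list(model.classes),
        "priors": model.priors.tolist(),
        "means": model.means.tolist(),
        "covariances": model.covariances.tolist(),
        "shrinkage": model.shrinkage,
        "feature_subset": list(model.feature_subset),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_model(path: str | Path) -> DiscriminantModel:
    payload = json.loads(Path(path).read_text())
    try:
        return DiscriminantModel(
            kind=payload["kind"],
            classes=list(payload["classes"]),
            priors=np.asarray(payload["priors"], dtype=float),
            means=np.asarray(payload["means"], dtype=float),
            covariances=np.asarray(payload["covariances"], dtype=float),
            shrinkage=float(payload["shrinkage"]),
            feature_subset=list(payload["feature_subset"]),
        )
    except KeyError as exc:
        raise IOError_(f"{path}: missing model field {exc}") from exc


def read_config(path: str | Path) -> dict:
    """Load a YAML config file as a nested dict."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise IOError_(f"{path}: config must be a mapping")
    return data


def write_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def set_dotted(config: dict, dotted_key: str, value) -> None:
    """Set a nested config entry by dotted key, e.g. ``simulate.seed``."""
    keys = dotted_key.split(".")
    node = config
    for k in keys[:-1]:
        node = node.setdefault(k, {})
        if not isinstance(node, dict):
            raise IOError_(f"config key {dotted_key!r} collides with a scalar")
    node[keys[-1]] = value
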