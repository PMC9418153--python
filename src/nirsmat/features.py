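"""144-feature extraction from the two filter branches.

Per subject, for each of the four signals (HbO, HHb, HbT, COE) on each
analysis channel (ch2, ch3) — eight signal×channel combinations — 18
features are computed:

* low-pass branch (6 raw + 6 normalized): the three pairwise stage mean
  differences (task−rest, recovery−rest, task−recovery), the two
  transition slopes (TB: least-squares slope over the first 8 s of the
  task stage; RB: first 8 s of the recovery stage) and their difference
  (TB − RB); the same six recomputed after min–max normalizing the
  full-record low-pass signal to [0, 1] (the "(01)" variants, which
  express change relative to the subject's own signal amplitude);
* band-pass branch (6): standard deviation, skewness and Pearson
  (non-excess) kurtosis of the task and recovery stages.

8 × 18 = 144 features, in a deterministic signal-major, channel-minor
column order.  Moments use 1/n (population) weighting; kurtosis is
non-excess (Gaussian → 3).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ANALYSIS_CHANNELS, SIGNALS, SignalBundle

MEAN_DIFF_PAIRS = {
    "task_rest_mean_d": ("task", "rest"),
    "recovery_rest_mean_d": ("recovery", "rest"),
    "task_recovery_mean_d": ("task", "recovery"),
}
LOWPASS_DESCRIPTORS = (
    "task_rest_mean_d",
    "recovery_rest_mean_d",
    "task_recovery_mean_d",
    "TB_slope",
    "RB_slope",
    "slope_d",
)
BANDPASS_DESCRIPTORS = (
    "task_std",
    "recovery_std",
    "task_skewness",
    "recovery_skewness",
    "task_kurtosis",
    "recovery_kurtosis",
)
SLOPE_WINDOW_SECONDS = 8.0


class FeatureError(ValueError):
    """Raised for invalid feature-extraction input."""


@dataclass(frozen=True)
class FeatureName:
    """Structured feature identifier with the canonical string form.

    Rendered e.g. ``"HbT_task_rest_mean_d (01, ch3)"`` for a normalized
    low-pass feature, ``"COE_recovery_skewness (ch3)"`` otherwise.
    """

    signal: str
    descriptor: str
    normalized: bool
    channel: str

    def __post_init__(self) -> None:
        if self.signal not in SIGNALS:
            raise FeatureError(f"unknown signal {self.signal!r}")
        if self.channel not in ANALYSIS_CHANNELS:
            raise FeatureError(f"unknown channel {self.channel!r}")
        if self.descriptor not in LOWPASS_DESCRIPTORS + BANDPASS_DESCRIPTORS:
            raise FeatureError(f"unknown descriptor {self.descriptor!r}")
        if self.normalized and self.descriptor not in LOWPASS_DESCRIPTORS:
            raise FeatureError(
                "the (01) normalized variant exists only for low-pass features"
            )

    def __str__(self) -> str:
        tag = f"(01, {self.channel})" if self.normalized else f"({self.channel})"
        return f"{self.signal}_{self.descriptor} {tag}"


_NAME_RE = re.compile(
    r"^\s*(HbO|HHb|HbT|COE)_([A-Za-z_]+?)\s*\(\s*(?:(01)\s*,\s*)?(ch[23])\s*\)\s*$"
)


def canonical_feature_name(name: str | FeatureName) -> str:
    """Normalize a feature-name string (whitespace-tolerant) to canonical form.

    Accepts e.g. ``"COE_TB_slope(01, ch2)"`` and returns
    ``"COE_TB_slope (01, ch2)"``.
    """
    if isinstance(name, FeatureName):
        return str(name)
    m = _NAME_RE.match(name)
    if not m:
        raise FeatureError(f"unparseable feature name {name!r}")
    signal, descriptor, norm, channel = m.groups()
    return str(FeatureName(signal, descriptor, norm is not None, channel))


def _feature_names() -> list[FeatureName]:
    names: list[FeatureName] = []
    for signal in SIGNALS:
        for channel in ANALYSIS_CHANNELS:
            for d in LOWPASS_DESCRIPTORS:
                names.append(FeatureName(signal, d, False, channel))
            for d in LOWPASS_DESCRIPTORS:
                names.append(FeatureName(signal, d, True, channel))
            for d in BANDPASS_DESCRIPTORS:
                names.append(FeatureName(signal, d, False, channel))
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(str(n) for n in _feature_names())
assert len(FEATURE_NAMES) == 144 and len(set(FEATURE_NAMES)) == 144


def stage_mean_difference(
    signal: np.ndarray,
    stages: dict[str, tuple[int, int]],
    pair: tuple[str, str],
) -> float:
    """mean(signal over first stage) − mean(signal over second stage)."""
    first, second = pair
    vals = []
    for stage in (first, second):
        lo, hi = stages[stage]
        if hi <= lo:
            raise FeatureError(f"stage {stage!r} is empty")
        vals.append(float(np.mean(signal[lo:hi])))
    return vals[0] - vals[1]


def transition_slope(
    signal: np.ndarray,
    boundary_sample: int,
    sampling_rate: float,
    window: float = SLOPE_WINDOW_SECONDS,
) -> float:
    """Least-squares slope (units/s) over ``window`` s after a stage boundary.

    The 8 s default window covers the reported 5–8 s latency to the peak
    optical response after stimulation.
    """
    n_win = round(window * sampling_rate)
    if boundary_sample + n_win > len(signal):
        raise FeatureError(
            f"slope window [{boundary_sample}, {boundary_sample + n_win}) "
            f"extends past the series end ({len(signal)} samples)"
        )
    y = np.asarray(signal[boundary_sample : boundary_sample + n_win], dtype=float)
    t = np.arange(n_win) / sampling_rate
    slope = np.polyfit(t, y, 1)[0]
    return float(slope)


def slope_difference(tb: float, rb: float) -> float:
    """Task-onset minus recovery-onset transition slope."""
    if not (np.isfinite(tb) and np.isfinite(rb)):
        raise FeatureError("slopes must be finite")
    return tb - rb


def normalize_01(signal: np.ndarray) -> np.ndarray:
    """Min–max rescale a series to [0, 1] over its full length."""
    x = np.asarray(signal, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise FeatureError("cannot min-max normalize a constant series")
    return (x - lo) / (hi - lo)


def _stage_values(
    signal: np.ndarray, stages: dict[str, tuple[int, int]], stage: str
) -> np.ndarray:
    lo, hi = stages[stage]
    vals = np.asarray(signal[lo:hi], dtype=float)
    if len(vals) < 3:
        raise FeatureError(f"stage {stage!r} has fewer than 3 samples")
    return vals


def stage_std(signal, stages, stage: str) -> float:
    """Population standard deviation of a stage segment."""
    return float(np.std(_stage_values(signal, stages, stage)))


def stage_skewness(signal, stages, stage: str) -> float:
    """Skewness m3/m2^(3/2) of a stage segment (1/n moments)."""
    vals = _stage_values(signal, stages, stage)
    if np.var(vals) == 0.0:
        raise FeatureError(f"stage {stage!r} has zero variance; skewness undefined")
    return float(stats.skew(vals, bias=True))


def stage_kurtosis(signal, stages, stage: str) -> float:
    """Pearson (non-excess) kurtosis m4/m2² of a stage segment."""
    vals = _stage_values(signal, stages, stage)
    if np.var(vals) == 0.0:
        raise FeatureError(f"stage {stage!r} has zero variance; kurtosis undefined")
    return float(stats.kurtosis(vals, fisher=False, bias=True))


def _lowpass_six(
    series: np.ndarray,
    stages: dict[str, tuple[int, int]],
    sampling_rate: float,
) -> dict[str, float]:
    out = {
        d: stage_mean_difference(series, stages, pair)
        for d, pair in MEAN_DIFF_PAIRS.items()
    }
    tb = transition_slope(series, stages["task"][0], sampling_rate)
    rb = transition_slope(series, stages["recovery"][0], sampling_rate)
    out["TB_slope"] = tb
    out["RB_slope"] = rb
    out["slope_d"] = slope_difference(tb, rb)
    return out


def extract_features(bundles: dict[str, SignalBundle]) -> dict[str, float]:
    """Extract the full 144-feature vector from a subject's two branches.

    Returns an ordered mapping from canonical feature name to value.
    Raises if any feature is non-finite, naming the offending feature.
    """
    lp, bp = bundles["lowpass"], bundles["bandpass"]
    fs = lp.sampling_rate
    values: dict[str, float] = {}
    for signal in SIGNALS:
        for channel in ANALYSIS_CHANNELS:
            raw = lp.signals[channel][signal]
            for d, v in _lowpass_six(raw, lp.stages, fs).items():
                values[str(FeatureName(signal, d, False, channel))] = v
            norm = normalize_01(raw)
            for d, v in _lowpass_six(norm, lp.stages, fs).items():
                values[str(FeatureName(signal, d, True, channel))] = v
            bseries = bp.signals[channel][signal]
            for stage in ("task", "recovery"):
                values[str(FeatureName(signal, f"{stage}_std", False, channel))] = (
                    stage_std(bseries, bp.stages, stage)
                )
                values[
                    str(FeatureName(signal, f"{stage}_skewness", False, channel))
                ] = stage_skewness(bseries, bp.stages, stage)
                values[
                    str(FeatureName(signal, f"{stage}_kurtosis", False, channel))
                ] = stage_kurtosis(bseries, bp.stages, stage)
    ordered = {name: values[name] for name in FEATURE_NAMES}
    for name, v in ordered.items():
        if not np.isfinite(v):
            raise FeatureError(f"feature {name!r} is not finite ({v})")
    return ordered


class FeatureTable:
    """Subjects × 144 named features with group labels and optional ages.

    Thin wrapper over a :class:`pandas.DataFrame` whose first columns
    are ``subject_id``, ``group`` and ``age``, followed by the 144
    feature columns in canonical order.
    """

    META_COLUMNS = ("subject_id", "group", "age")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.META_COLUMNS if c not in df.columns]
        if missing:
            raise FeatureError(f"feature table missing columns {missing}")
        feature_cols = [c for c in df.columns if c not in self.META_COLUMNS]
        if tuple(feature_cols) != FEATURE_NAMES:
            raise FeatureError(
                "feature table must contain exactly the 144 canonical feature "
                f"columns in order; got {len(feature_cols)} columns"
            )
        if df[list(FEATURE_NAMES)].isna().any().any():
            raise FeatureError("feature table contains NaN feature values")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> np.ndarray:
        return self.df["group"].to_numpy()

    @property
    def ages(self) -> np.ndarray:
        return self.df["age"].to_numpy(dtype=float)

    def matrix(self, features: list[str] | None = None) -> np.ndarray:
        cols = (
            [canonical_feature_name(f) for f in features]
            if features is not None
            else list(FEATURE_NAMES)
        )
        return self.df[cols].to_numpy(dtype=float)

    def feature(self, name: str) -> np.ndarray:
        return self.df[canonical_feature_name(name)].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.df.loc[mask].reset_index(drop=True))


def extract_feature_table(recordings, bundles_fn=None) -> FeatureTable:
    """Preprocess and extract features for a whole cohort.

    ``bundles_fn`` maps a recording to its branch bundles (defaults to
    :func:`nirsmat.preprocess.preprocess_recording`).
    """
    from .preprocess import preprocess_recording

    bundles_fn = bundles_fn or preprocess_recording
    rows = []
    for rec in recordings:
        row = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "age": rec.age if rec.age is not None else np.nan,
        }
        row.update(extract_features(bundles_fn(rec)))
        rows.append(row)
    return FeatureTable(pd.DataFrame(rows))


def correlate_feature_with_age(table: FeatureTable, feature: str) -> float:
    """Pearson correlation between a z-scored feature and subject age.

    Diagnostic for age confounding: group ages differ, so a feature
    driven by age rather than pathology would correlate here.
    """
    ages = table.ages
    ok = np.isfinite(ages)
    if ok.sum() < 3:
        raise FeatureError("need at least 3 subjects with recorded ages")
    x = table.feature(feature)[ok]
    if np.std(x) == 0.0 or np.std(ages[ok]) == 0.0:
        raise FeatureError("zero variance; correlation undefined")
    z = (x - x.mean()) / x.std()
    r, _ = stats.pearsonr(z, ages[ok])
    return float(r)
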