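"""Dual-branch Butterworth preprocessing and MAT stage segmentation.

Two filters are applied in parallel to each hemoglobin series:

* a low-pass branch (4th-order Butterworth, 0.1 Hz cutoff) that removes
  cardiac (~1 Hz), respiratory (~0.3 Hz) and Mayer-wave (~0.1 Hz)
  oscillations and keeps the slow task-level hemodynamic trend;
* a band-pass branch (4th-order Butterworth, 0.01–0.3 Hz) that isolates
  the per-stimulus hemodynamic response band.

Both are applied forward and backward (zero-phase), so stage boundaries
are not shifted by group delay; the effective magnitude response is the
squared Butterworth response.  From each filtered HbO/HHb pair the two
derived signals are formed: total hemoglobin HbT = HbO + HHb (a blood
volume proxy) and cerebral oxygen exchange COE = HHb − HbO.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .protocol import MATProtocol
from .simulate import Recording

ANALYSIS_CHANNELS = ("ch2", "ch3")
SIGNALS = ("HbO", "HHb", "HbT", "COE")


class PreprocessError(ValueError):
    """Raised for invalid filtering or segmentation input."""


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter settings.

    ``cutoffs`` is a single corner frequency (Hz) for a low-pass, or a
    ``(low, high)`` pair for a band-pass.  ``zero_phase`` selects
    forward-backward application.
    """

    kind: str = "lowpass"
    order: int = 4
    cutoffs: float | tuple[float, float] = 0.1
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "bandpass"):
            raise PreprocessError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise PreprocessError("filter order must be >= 1")
        cut = np.atleast_1d(np.asarray(self.cutoffs, dtype=float))
        if self.kind == "lowpass" and cut.size != 1:
            raise PreprocessError("lowpass takes a single cutoff")
        if self.kind == "bandpass":
            if cut.size != 2:
                raise PreprocessError("bandpass takes a (low, high) pair")
            if cut[0] >= cut[1]:
                raise PreprocessError("bandpass requires low < high")
        if np.any(cut <= 0):
            raise PreprocessError("cutoff frequencies must be positive")

    def validate_rate(self, sampling_rate: float) -> None:
        cut = np.atleast_1d(np.asarray(self.cutoffs, dtype=float))
        if np.any(cut >= sampling_rate / 2.0):
            raise PreprocessError(
                f"cutoffs {self.cutoffs} must be below the Nyquist frequency "
                f"{sampling_rate / 2.0} Hz"
            )


LOWPASS_SPEC = FilterSpec(kind="lowpass", order=4, cutoffs=0.1)
BANDPASS_SPEC = FilterSpec(kind="bandpass", order=4, cutoffs=(0.01, 0.3))


def apply_filter(
    series: np.ndarray,
    sampling_rate: float,
    spec: FilterSpec,
    pad_seconds: float = 10.0,
) -> np.ndarray:
    """Filter one time series, preserving its length.

    Zero-phase application uses reflective ("even") padding of
    ``pad_seconds`` (at least one filter warm-up length) so the 555 s
    records keep edge transients negligible away from the boundaries.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise PreprocessError("series must be one-dimensional")
    min_len = 3 * (spec.order + 1) + 1
    if len(x) < min_len:
        raise PreprocessError(
            f"series of length {len(x)} too short for order-{spec.order} "
            f"filtering; at least {min_len} samples required"
        )
    if not np.all(np.isfinite(x)):
        raise PreprocessError("series contains NaN or infinite values")
    spec.validate_rate(sampling_rate)
    sos = sps.butter(
        spec.order, spec.cutoffs, btype=spec.kind, fs=sampling_rate, output="sos"
    )
    if spec.zero_phase:
        padlen = min(len(x) - 1, max(int(pad_seconds * sampling_rate), min_len))
        return sps.sosfiltfilt(x=x, sos=sos, padtype="even", padlen=padlen)
    return sps.sosfilt(sos, x)


def derive_signals(hbo: np.ndarray, hhb: np.ndarray) -> dict[str, np.ndarray]:
    """Form the four analysis signals from an HbO/HHb pair.

    HbT = HbO + HHb; COE = HHb − HbO (oxygenation drop ⇒ COE rise).
    """
    hbo = np.asarray(hbo, dtype=float)
    hhb = np.asarray(hhb, dtype=float)
    if hbo.shape != hhb.shape:
        raise PreprocessError(
            f"HbO and HHb lengths differ: {hbo.shape} vs {hhb.shape}"
        )
    return {"HbO": hbo, "HHb": hhb, "HbT": hbo + hhb, "COE": hhb - hbo}


def segment_stages(
    n_samples: int, sampling_rate: float, protocol: MATProtocol
) -> dict[str, tuple[int, int]]:
    """Half-open sample intervals of the rest/task/recovery stages.

    The intervals partition ``[0, n_samples)`` exactly.  ``n_samples``
    may deviate from the protocol's expected length by at most one
    sample (rounding at acquisition).
    """
    expected = round(protocol.total_duration * sampling_rate)
    if abs(n_samples - expected) > 1:
        raise PreprocessError(
            f"series has {n_samples} samples but the protocol implies "
            f"{expected} at {sampling_rate} Hz"
        )
    r = round(protocol.rest_duration * sampling_rate)
    t = round((protocol.rest_duration + protocol.task_duration) * sampling_rate)
    return {"rest": (0, r), "task": (r, t), "recovery": (t, n_samples)}


@dataclass
class SignalBundle:
    """One filter branch's four derived signals on the analysis channels.

    ``signals[channel][signal_name]`` holds the filtered series for
    channel ∈ {ch2, ch3} and signal ∈ {HbO, HHb, HbT, COE};
    ``stages`` holds the half-open sample intervals of the three MAT
    stages, which partition the record.
    """

    branch: str
    signals: dict[str, dict[str, np.ndarray]]
    stages: dict[str, tuple[int, int]]
    sampling_rate: float = 17.0

    def stage_slice(self, channel: str, signal: str, stage: str) -> np.ndarray:
        lo, hi = self.stages[stage]
        return self.signals[channel][signal][lo:hi]


def preprocess_recording(
    rec: Recording,
    lowpass_spec: FilterSpec = LOWPASS_SPEC,
    bandpass_spec: FilterSpec = BANDPASS_SPEC,
) -> dict[str, SignalBundle]:
    """Run both filter branches on a recording's analysis channels.

    Per branch: filter HbO and HHb, derive HbT/COE from the filtered
    pair, attach the stage segmentation.  Only ch2 (Fp1, left PFC) and
    ch3 (Fp2, right PFC) are retained for analysis.
    """
    stages = segment_stages(rec.n_samples, rec.sampling_rate, rec.protocol)
    bundles: dict[str, SignalBundle] = {}
    for branch, spec in (("lowpass", lowpass_spec), ("bandpass", bandpass_spec)):
        per_channel: dict[str, dict[str, np.ndarray]] = {}
        for ch in ANALYSIS_CHANNELS:
            hbo_f = apply_filter(rec.hbo[ch], rec.sampling_rate, spec)
            hhb_f = apply_filter(rec.hhb[ch], rec.sampling_rate, spec)
            per_channel[ch] = derive_signals(hbo_f, hhb_f)
        bundles[branch] = SignalBundle(
            branch=branch,
            signals=per_channel,
            stages=stages,
            sampling_rate=rec.sampling_rate,
        )
    return bundles
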