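"""Synthetic fNIRS cohort generator for the MAT protocol.

No public fNIRS migraine dataset accompanies this pipeline, so cohorts
are simulated with the statistical structure the downstream analysis
assumes:

* a task-evoked hemodynamic response — a canonical double-gamma HRF
  (peak ~6 s, inside the 5–8 s latency window reported for PFC optical
  responses) convolved with one unit impulse per arithmetic cycle;
* anti-correlated HbO/HHb via a neurovascular coupling ratio, so that
  total hemoglobin (HbT = HbO + HHb) and cerebral oxygen exchange
  (COE = HHb − HbO) carry distinct information;
* additive physiological noise: sinusoids at the cardiac (~1 Hz),
  respiratory (~0.3 Hz) and Mayer-wave (~0.1 Hz) bands with random
  phases, a slow polynomial drift, and white Gaussian noise;
* group-dependent effect structure: migraineurs (CM, MOH) respond with
  larger right-PFC (ch3) blood-volume increases than healthy controls;
  MOH additionally shows elevated cycle-to-cycle response variability
  at ch3 and a stronger left-PFC (ch2) COE transient at task onset,
  with the two subject-level factors correlated (the "band-shaped"
  MOH structure) at a configurable strength.

Channels follow the 10–20 montage of the four-channel PFC headgear:
ch1 ≙ F7, ch2 ≙ Fp1 (left PFC), ch3 ≙ Fp2 (right PFC), ch4 ≙ F8.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .protocol import MATProtocol, build_protocol

GROUPS = ("HC", "CM", "MOH")
CHANNELS = ("ch1", "ch2", "ch3", "ch4")
CHANNEL_POSITIONS = {"ch1": "F7", "ch2": "Fp1", "ch3": "Fp2", "ch4": "F8"}

# Per-group age distributions (mean, sd) in years, truncated to [20, 60].
AGE_DISTRIBUTIONS = {"HC": (44.9, 8.7), "CM": (34.8, 10.9), "MOH": (45.8, 11.2)}

_DEFAULT_EVOKED = {
    # HbO response amplitude (a.u.) per group and channel.  Migraine
    # groups respond more strongly at the right PFC (ch3) than HC; the
    # lateral channels carry a weak response and are not analysed.
    "HC": {"ch1": 0.2, "ch2": 0.3, "ch3": 0.3, "ch4": 0.2},
    "CM": {"ch1": 0.2, "ch2": 0.3, "ch3": 1.0, "ch4": 0.2},
    "MOH": {"ch1": 0.2, "ch2": 0.3, "ch3": 1.0, "ch4": 0.2},
}

# Cycle-to-cycle multiplicative jitter (sd of the per-cycle response
# scale) — drives in-band HbO fluctuation during the task stage.
_DEFAULT_CYCLE_JITTER = {"HC": 0.10, "CM": 0.12, "MOH": 0.60}

# Sustained COE transient at ch2 after task onset (a.u.) — drives the
# normalized COE task-onset slope.
_DEFAULT_ONSET_GAIN = {"HC": 0.05, "CM": 0.10, "MOH": 0.60}

_DEFAULT_NOISE_AMPLITUDES = {
    "cardiac": 0.30,
    "respiratory": 0.20,
    "mayer": 0.20,
    "drift": 0.30,
    "white": 0.15,
}
_DEFAULT_NOISE_FREQUENCIES = {"cardiac": 1.0, "respiratory": 0.3, "mayer": 0.1}


class SimulationError(ValueError):
    """Raised for invalid simulation settings."""


@dataclass(frozen=True)
class SimulationParams:
    """Tunable settings of the synthetic cohort generator.

    Amplitudes are in the same arbitrary concentration units as the
    hemoglobin series; frequencies in Hz; delays in seconds.
    """

    sampling_rate: float = 17.0
    baseline_hbo: float = 10.0
    baseline_hhb: float = 5.0
    hrf_peak_delay: float = 6.0
    hrf_undershoot_delay: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    evoked_amplitude_by_group_and_channel: dict = field(
        default_factory=lambda: {g: dict(c) for g, c in _DEFAULT_EVOKED.items()}
    )
    evoked_amplitude_sd: float = 0.10
    cycle_jitter_by_group: dict = field(
        default_factory=lambda: dict(_DEFAULT_CYCLE_JITTER)
    )
    onset_gain_by_group: dict = field(
        default_factory=lambda: dict(_DEFAULT_ONSET_GAIN)
    )
    onset_time_constant: float = 10.0
    coupling_ratio: float = 0.3
    moh_correlation: float = 0.9
    subject_factor_sd: float = 0.4
    noise_amplitudes: dict = field(
        default_factory=lambda: dict(_DEFAULT_NOISE_AMPLITUDES)
    )
    noise_frequencies: dict = field(
        default_factory=lambda: dict(_DEFAULT_NOISE_FREQUENCIES)
    )
    drift_degree: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2.0:
            raise SimulationError(
                "sampling_rate must exceed 2 Hz (Nyquist for the 0.01-0.3 Hz "
                "analysis band and sub-Hz physiological noise)"
            )
        if not 0.0 <= self.moh_correlation <= 1.0:
            raise SimulationError("moh_correlation must lie in [0, 1]")
        for name, amp in self.noise_amplitudes.items():
            if amp < 0:
                raise SimulationError(f"noise amplitude {name!r} must be >= 0")
        for group, chans in self.evoked_amplitude_by_group_and_channel.items():
            for ch, amp in chans.items():
                if amp < 0:
                    raise SimulationError(
                        f"evoked amplitude for {group}/{ch} must be >= 0"
                    )


@dataclass
class Recording:
    """One subject's multichannel HbO/HHb time series with metadata."""

    subject_id: str
    group: str
    sampling_rate: float
    protocol: MATProtocol
    hbo: dict[str, np.ndarray]
    hhb: dict[str, np.ndarray]
    age: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS + ("UNKNOWN",):
            raise SimulationError(f"unknown group {self.group!r}")
        lengths = {len(v) for v in self.hbo.values()}
        lengths |= {len(v) for v in self.hhb.values()}
        if len(lengths) != 1:
            raise SimulationError("all channel series must share one length")
        expected = round(self.protocol.total_duration * self.sampling_rate)
        (n,) = lengths
        if abs(n - expected) > 1:
            raise SimulationError(
                f"series length {n} inconsistent with protocol "
                f"({expected} samples expected)"
            )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.hbo.values())))

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


def double_gamma_hrf(params: SimulationParams) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1.

    Positive gamma peaking at ``hrf_peak_delay`` minus a smaller gamma
    peaking at ``hrf_undershoot_delay`` (the post-stimulus undershoot).
    Sampled at the recording rate over a 32 s support.
    """
    fs = params.sampling_rate
    t = np.arange(0.0, 32.0, 1.0 / fs)
    # gamma pdf with scale 1 peaks at shape-1, so shape = delay + 1
    peak = stats.gamma.pdf(t, a=params.hrf_peak_delay + 1.0)
    under = stats.gamma.pdf(t, a=params.hrf_undershoot_delay + 1.0)
    h = peak - params.hrf_undershoot_ratio * under
    return h / h.max()


def _evoked_response(
    protocol: MATProtocol,
    params: SimulationParams,
    n_samples: int,
    cycle_scales: np.ndarray,
) -> np.ndarray:
    """Unit-amplitude evoked HbO response: HRF ⊛ per-cycle impulse train."""
    fs = params.sampling_rate
    train = np.zeros(n_samples)
    for onset, scale in zip(protocol.cycle_onsets(), cycle_scales):
        idx = round(onset * fs)
        if idx < n_samples:
            train[idx] += scale
    return np.convolve(train, double_gamma_hrf(params))[:n_samples]


def _onset_transient(
    protocol: MATProtocol, params: SimulationParams, n_samples: int
) -> np.ndarray:
    """Unit-amplitude sustained transient rising at task onset.

    Saturating exponential with time constant ``onset_time_constant``
    through the task stage, decaying with the same constant in recovery.
    """
    fs = params.sampling_rate
    t = np.arange(n_samples) / fs
    tau = params.onset_time_constant
    t_on, t_off = protocol.stage_boundaries()["task"]
    y = np.zeros(n_samples)
    during = (t >= t_on) & (t < t_off)
    y[during] = 1.0 - np.exp(-(t[during] - t_on) / tau)
    after = t >= t_off
    level = 1.0 - np.exp(-(t_off - t_on) / tau)
    y[after] = level * np.exp(-(t[after] - t_off) / tau)
    return y


def _noise(
    rng: np.random.Generator, params: SimulationParams, n_samples: int
) -> np.ndarray:
    """Physiological + instrumental noise for one channel series."""
    fs = params.sampling_rate
    t = np.arange(n_samples) / fs
    y = np.zeros(n_samples)
    for band, freq in params.noise_frequencies.items():
        amp = params.noise_amplitudes.get(band, 0.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        y += amp * np.sin(2.0 * np.pi * freq * t + phase)
    drift_amp = params.noise_amplitudes.get("drift", 0.0)
    if drift_amp > 0:
        x = t / t[-1] if n_samples > 1 else t
        coefs = rng.normal(0.0, drift_amp, size=params.drift_degree + 1)
        y += np.polynomial.polynomial.polyval(x, coefs)
    else:
        # keep the stream position independent of drift_amp
        rng.normal(0.0, 1.0, size=params.drift_degree + 1)
    white = params.noise_amplitudes.get("white", 0.0)
    y += white * rng.standard_normal(n_samples)
    return y


def _truncated_normal_age(rng: np.random.Generator, group: str) -> float:
    mean, sd = AGE_DISTRIBUTIONS[group]
    for _ in range(1000):
        age = rng.normal(mean, sd)
        if 20.0 <= age <= 60.0:
            return float(age)
    return float(np.clip(rng.normal(mean, sd), 20.0, 60.0))


def simulate_subject(
    group: str,
    protocol: MATProtocol | None = None,
    params: SimulationParams | None = None,
    subject_seed: int = 0,
    subject_id: str | None = None,
) -> Recording:
    """Simulate one subject's four-channel HbO/HHb recording.

    The recording is fully determined by ``(group, protocol, params,
    subject_seed)``; identical inputs give bit-identical output.
    """
    if group not in GROUPS:
        raise SimulationError(f"unknown group {group!r}; expected one of {GROUPS}")
    protocol = protocol or build_protocol()
    params = params or SimulationParams()
    rng = np.random.default_rng(subject_seed)
    fs = params.sampling_rate
    n = round(protocol.total_duration * fs)

    # subject-level factors: correlated lognormal pair drives the MOH
    # variability/onset-slope association; uncorrelated for other groups
    rho = params.moh_correlation if group == "MOH" else 0.0
    z1 = rng.standard_normal()
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal()
    f_var = float(np.exp(params.subject_factor_sd * z1))
    f_slope = float(np.exp(params.subject_factor_sd * z2))

    jitter_sd = params.cycle_jitter_by_group.get(group, 0.0) * f_var
    cycle_scales = 1.0 + jitter_sd * rng.standard_normal(protocol.n_cycles)
    evoked_unit = _evoked_response(protocol, params, n, cycle_scales)
    onset_unit = _onset_transient(protocol, params, n)
    onset_gain = params.onset_gain_by_group.get(group, 0.0) * f_slope

    amplitudes = params.evoked_amplitude_by_group_and_channel[group]
    hbo: dict[str, np.ndarray] = {}
    hhb: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        amp = amplitudes.get(ch, 0.0) + params.evoked_amplitude_sd * rng.standard_normal()
        evoked = amp * evoked_unit
        hbo_ch = params.baseline_hbo + evoked + _noise(rng, params, n)
        hhb_ch = (
            params.baseline_hhb
            - params.coupling_ratio * evoked
            + _noise(rng, params, n)
        )
        if ch == "ch2":
            # COE (= HHb - HbO) rises after task onset, strongest in MOH
            hhb_ch = hhb_ch + onset_gain * onset_unit
        hbo[ch] = hbo_ch
        hhb[ch] = hhb_ch

    age = _truncated_normal_age(rng, group)
    return Recording(
        subject_id=subject_id or f"{group}_{subject_seed}",
        group=group,
        sampling_rate=fs,
        protocol=protocol,
        hbo=hbo,
        hhb=hhb,
        age=age,
    )


def simulate_cohort(
    n_hc: int = 13,
    n_cm: int = 9,
    n_moh: int = 12,
    params: SimulationParams | None = None,
    seed: int | None = None,
    protocol: MATProtocol | None = None,
) -> list[Recording]:
    """Simulate a labelled cohort (defaults: 13 HC, 9 CM, 12 MOH).

    Per-subject seeds are ``cohort_seed + stable offset`` so enlarging
    one group never perturbs subjects simulated before it.
    """
    if min(n_hc, n_cm, n_moh) < 0:
        raise SimulationError("group counts must be >= 0")
    params = params or SimulationParams()
    cohort_seed = params.seed if seed is None else seed
    protocol = protocol or build_protocol()
    # disjoint stable offset blocks per group, 10_000 slots each
    blocks = {"HC": 0, "CM": 10_000, "MOH": 20_000}
    recordings: list[Recording] = []
    for group, count in (("HC", n_hc), ("CM", n_cm), ("MOH", n_moh)):
        for i in range(count):
            subject_seed = cohort_seed + blocks[group] + i
            recordings.append(
                simulate_subject(
                    group,
                    protocol=protocol,
                    params=params,
                    subject_seed=subject_seed,
                    subject_id=f"{group}{i + 1:02d}",
                )
            )
    return recordings


def with_params(params: SimulationParams, **changes) -> SimulationParams:
    """Return a copy of ``params`` with the given fields replaced."""
    return replace(params, **changes)
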