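import numpy as np
import pandas as pd
import pytest

from nirsmat import (
    FEATURE_NAMES,
    FeatureTable,
    SimulationParams,
    extract_feature_table,
    simulate_cohort,
)


def quiet_params(**overrides) -> SimulationParams:
    """Params with every stochastic/nuisance component switched off."""
    base = dict(
        noise_amplitudes={k: 0.0 for k in ("cardiac", "respiratory", "mayer", "drift", "white")},
        evoked_amplitude_sd=0.0,
        cycle_jitter_by_group={"HC": 0.0, "CM": 0.0, "MOH": 0.0},
        onset_gain_by_group={"HC": 0.0, "CM": 0.0, "MOH": 0.0},
        subject_factor_sd=0.0,
    )
    base.update(overrides)
    return SimulationParams(**base)


def make_feature_table(labels, rng, informative=None) -> FeatureTable:
    """Random feature table with optional per-class offsets planted into
    named columns (``informative`` maps feature name -> {label: mean})."""
    n = len(labels)
    df = pd.DataFrame(
        rng.normal(size=(n, len(FEATURE_NAMES))), columns=list(FEATURE_NAMES)
    )
    for name, means in (informative or {}).items():
        for label, mu in means.items():
            mask = np.asarray(labels) == label
            df.loc[mask, name] = mu + 0.3 * rng.normal(size=int(mask.sum()))
    df.insert(0, "age", rng.uniform(20, 60, size=n))
    df.insert(0, "group", list(labels))
    df.insert(0, "subject_id", [f"s{i}" for i in range(n)])
    return FeatureTable(df)


@pytest.fixture(scope="session")
def default_table() -> FeatureTable:
    """Features of the default 34-subject cohort at the default seed."""
    cohort = simulate_cohort(seed=SimulationParams().seed)
    return extract_feature_table(cohort)
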