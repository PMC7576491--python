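import pandas as pd
import pytest

from pahrisk.congeners import load_registry
from pahrisk.synthetic import GeneratorSpec, generate_cohort


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort, fixed seed, shared across tests."""
    return generate_cohort(GeneratorSpec(seed=1))


@pytest.fixture(scope="session")
def personal_samples(cohort):
    s = cohort.samples
    return s[s["sampler_kind"] == "personal"].reset_index(drop=True)


def make_sample_row(registry, season="heating", sampler_kind="personal",
                    duration_h=24.0, pm25=230.0, **congeners) -> pd.Series:
    """One samples-table row with all congeners defaulting to 0."""
    row = {"sample_id": "S1", "season": season, "sampler_kind": sampler_kind,
           "participant_id": "P1", "duration_h": duration_h, "pm25": pm25}
    row.update({a: 0.0 for a in registry.abbreviations})
    row.update(congeners)
    return pd.Series(row)
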