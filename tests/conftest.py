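import numpy as np
import pandas as pd
import pytest

from emoprofile import default_effects, generate


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One synthetic cohort at the default study conditions (107 animals)."""
    return generate(default_effects(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_cohort_df() -> pd.DataFrame:
    """Six-animal cohort covering every design cell, hand-written."""
    rows = []
    for i, (pren, env) in enumerate(
        [("SAL", "ST"), ("SAL", "UE"), ("SAL", "PE"), ("VPA", "ST"), ("VPA", "UE"), ("VPA", "PE")]
    ):
        rows.append(
            dict(
                animal_id=f"A{i}", litter_id=f"L{i % 3}", prenatal=pren, environment=env,
                batch=i % 3 + 1,
                open_arm_time=20.0 + i, training_freezing=30.0 + i,
                context_freezing_lt=40.0 + 2 * i, pretone_freezing_lt=25.0 + i,
                tone_freezing_lt=50.0 - i, social_preference=0.6 + 0.01 * i,
                hotplate_latency=9.0 + 0.5 * i, epm_distance=1400.0 + 10 * i,
                head_dips=7.0 + i, perseveration=(i == 3),
            )
        )
    df = pd.DataFrame(rows)
    df["perseveration"] = df["perseveration"].astype("boolean")
    return df
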