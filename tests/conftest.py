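import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ssgblup import simdata
from ssgblup.pedigree import UNKNOWN, PedigreeTable

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_random_pedigree(rng: np.random.Generator, n: int, n_founders: int = 10) -> PedigreeTable:
    """Random valid pedigree: animal i's parents drawn among 0..i-1."""
    sire = np.full(n, UNKNOWN, dtype=np.int64)
    dam = np.full(n, UNKNOWN, dtype=np.int64)
    sex = np.array(["M" if rng.random() < 0.5 else "F" for _ in range(n)], dtype=object)
    sex[:n_founders] = ["M", "F"] * (n_founders // 2) + ["M"] * (n_founders % 2)
    for i in range(n_founders, n):
        males = [j for j in range(i) if sex[j] == "M"]
        females = [j for j in range(i) if sex[j] == "F"]
        if males and rng.random() < 0.9:
            sire[i] = rng.choice(males)
        if females and rng.random() < 0.9:
            dam[i] = rng.choice(females)
    return PedigreeTable(
        ids=np.array([f"a{i}" for i in range(n)], dtype=object),
        sire=sire,
        dam=dam,
        birth_year=np.arange(n) // max(n // 5, 1) + 2000,
        breed=np.full(n, "alpine", dtype=object),
        sex=sex,
    )


@pytest.fixture(scope="session")
def small_sim() -> simdata.SimOutput:
    """Moderate two-breed population shared across test modules."""
    cfg = simdata.SimConfig(
        n_founders_per_breed=60,
        n_generations=2,
        n_sires_per_gen=8,
        n_daughters_per_sire=10,
        n_sons_per_sire=3,
        n_snps=600,
        seed=12345,
    )
    return simdata.simulate_population(cfg)


@pytest.fixture
def trio_pedigree() -> PedigreeTable:
    return PedigreeTable.from_frame(
        pd.DataFrame(
            {
                "animal": ["sire", "dam", "kid"],
                "sire": [0, 0, "sire"],
                "dam": [0, 0, "dam"],
                "birth_year": [2000, 2000, 2002],
                "breed": ["alpine"] * 3,
                "sex": ["M", "F", "F"],
            }
        )
    )
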