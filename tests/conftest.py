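import numpy as np
import pandas as pd
import pytest

from intersoil import OtuSimSpec, SoilSimSpec, published_tables, \
    simulate_otu, simulate_soil


@pytest.fixture(scope="session")
def soil_fixture():
    """Published soil-table pseudo-replicates (36 samples, 10 variables)."""
    soil, _ = published_tables()
    return soil


@pytest.fixture(scope="session")
def tea_fixture():
    _, tea = published_tables()
    return tea


@pytest.fixture()
def small_soil_spec():
    return SoilSimSpec(
        variables={"AN": (20.0, 0.5), "AK": (150.0, 5.0), "pH": (4.8, 0.05)},
        effects={("T1", 2): {"AN": 5.0}},
        n_replicates=3)


@pytest.fixture()
def blocky_otu():
    """3 planted blocks of 10 OTUs at rho=0.9, 40 samples."""
    spec = OtuSimSpec(
        n_samples_per_group={"G": 40}, n_otus=30,
        blocks=[list(range(10)), list(range(10, 20)), list(range(20, 30))],
        rho=0.9, depth=5000)
    return simulate_otu(spec, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def measurement_frame(values: dict, treatments=("CK", "T1", "T2"),
                      periods=(1,), reps=3) -> pd.DataFrame:
    """Helper: tidy frame from {variable: per-sample values}."""
    n = len(treatments) * len(periods) * reps
    rows = []
    i = 0
    for trt in treatments:
        for p in periods:
            for r in range(1, reps + 1):
                rows.append({"sample_id": f"{trt}.P{p}.R{r}",
                             "treatment": trt, "period": p, "replicate": r,
                             **{k: v[i] for k, v in values.items()}})
                i += 1
    assert all(len(v) == n for v in values.values())
    return pd.DataFrame(rows)
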