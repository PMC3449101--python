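import numpy as np
import pandas as pd
import pytest

from swatcna import (
    ClassificationTable,
    PlantedEvent,
    ProbeMatrix,
    SimSpec,
    figure1_fixture,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def figure1():
    """The deterministic 6-sample x 20-probe toy experiment."""
    return figure1_fixture()


@pytest.fixture(scope="session")
def planted_cohort():
    """12-sample cohort, 2 chromosomes x 500 probes, one gain + one loss."""
    spec = SimSpec(
        n_samples=12,
        n_probes=500,
        n_chromosomes=2,
        events=[
            PlantedEvent("1", 150, 190, "gain", amplitude=0.58, prevalence=0.5),
            PlantedEvent("2", 80, 105, "loss", amplitude=-0.8, prevalence=0.45),
        ],
        noise_sd=0.1,
        seed=11,
    )
    pm, truth = simulate_cohort(spec)
    return pm, truth, spec


def make_probe_matrix(values: np.ndarray, chromosome: str = "1") -> ProbeMatrix:
    """ProbeMatrix from a raw probes x samples array on one chromosome."""
    n_probes, n_samples = values.shape
    probes = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n_probes)],
            "chromosome": chromosome,
            "start_bp": np.arange(n_probes) * 100_000,
            "end_bp": np.arange(n_probes) * 100_000 + 60,
        }
    )
    log2 = pd.DataFrame(values, columns=[f"S{j}" for j in range(n_samples)])
    return ProbeMatrix.from_frames(probes, log2)


def make_direction_table(values: np.ndarray) -> pd.DataFrame:
    """Direction table ({-1,0,1}) aligned with make_probe_matrix output."""
    n_probes, n_samples = values.shape
    return pd.DataFrame(
        values.astype(np.int8),
        index=pd.RangeIndex(n_probes),
        columns=[f"S{j}" for j in range(n_samples)],
    )


def brute_force_pws(direction_values: np.ndarray, w: int, dir_value: int) -> np.ndarray:
    """O(windows x w x samples) reference counter for probe window scores."""
    n_probes, n_samples = direction_values.shape
    scores = []
    for start in range(n_probes - w + 1):
        count = 0
        for j in range(n_samples):
            if all(direction_values[start + k, j] == dir_value for k in range(w)):
                count += 1
        scores.append(100.0 * count / n_samples)
    return np.array(scores)
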