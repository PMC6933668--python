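import numpy as np
import pytest

from lignokin import BatchCondition, ModelParams
from lignokin.synthetic import DEFAULT_BACKGROUND, NoiseModel, generate_batch_set


@pytest.fixture(scope="session")
def reference_params() -> ModelParams:
    """Best-fit parameter set for the pretreated corn-stover system."""
    return ModelParams()


@pytest.fixture(scope="session")
def reference_condition() -> BatchCondition:
    """Reference batch: 10% solids, 20 mg/g enzyme, background liquor."""
    return BatchCondition(lambda_E=0.020, f_is0=0.10, **DEFAULT_BACKGROUND)


@pytest.fixture(scope="session")
def noiseless_batch_set(reference_params):
    """The full batch campaign simulated exactly (no measurement noise)."""
    return generate_batch_set(
        reference_params, noise=NoiseModel(rel_sd_sugars=0.0, rel_sd_fis=0.0, seed=0)
    )


def random_state_arrays(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random physically valid 9-component state vectors.

    Insoluble fractions total up to ~0.2, solubles up to a few percent,
    enzyme up to ~2e-3 — the operating envelope of the experiments.
    """
    out = np.empty((n, 9))
    for i in range(n):
        insol = rng.dirichlet(np.ones(5)) * rng.uniform(0.02, 0.20)
        sol = rng.uniform(0.0, 0.02, size=3)
        f_ET = rng.uniform(0.0, 2e-3)
        out[i] = np.concatenate([insol, sol, [f_ET]])
    return out
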