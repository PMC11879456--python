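import numpy as np
import pytest

from rtfit import RTFParams, TimeScale, build_problem, simulate
from rtfit.simulate import SimSpec, default_single_dose_truth


@pytest.fixture(scope="session")
def default_truth() -> RTFParams:
    return default_single_dose_truth()


@pytest.fixture(scope="session")
def scale() -> TimeScale:
    return TimeScale(10.0)


@pytest.fixture(scope="session")
def noisy_table():
    """Default simulated single-dose dataset (21 points, 2% noise)."""
    table, record = simulate(SimSpec(seed=0))
    return table, record


@pytest.fixture(scope="session")
def fitted_default(noisy_table):
    """A multi-start fit of the default dataset, shared across tests."""
    from rtfit import fit

    table, _ = noisy_table
    problem = build_problem(table, "singleDose", sign_sus=+1, sign_trans=+1)
    return fit(problem, n_starts=30, seed=1)


def random_params(rng: np.random.Generator) -> RTFParams:
    """A random interior single-dose parameter point for gradient checks."""
    return RTFParams(
        A=rng.uniform(0.2, 2.0),
        B=rng.uniform(0.2, 2.0),
        alpha=10 ** rng.uniform(-1, 1),
        beta=10 ** rng.uniform(-1, 1),
        gamma=10 ** rng.uniform(-1, 1),
        tau=rng.uniform(-1.5, 2.0),
        b=rng.uniform(-1.0, 1.0),
        signSus=int(rng.choice([-1, 1])),
        signTrans=int(rng.choice([-1, 1])),
    )
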