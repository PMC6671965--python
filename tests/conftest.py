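"""Shared fixtures: seeded Monte-Carlo ensembles reused across tests.

The ensembles are the expensive part of the suite, so one per network
size is computed once per session at a fixed master seed and shared.
2000 runs keeps binomial standard errors around one percentage point
for the frequency statistics.
"""

import numpy as np
import pytest

import signedbalance as sb

ENSEMBLE_RUNS = 2000
MASTER_SEED = 1


@pytest.fixture(scope="session")
def ensemble_n7() -> sb.EnsembleResult:
    return sb.run_ensemble(7, ENSEMBLE_RUNS, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def ensemble_n9() -> sb.EnsembleResult:
    return sb.run_ensemble(9, ENSEMBLE_RUNS, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def ensemble_n11() -> sb.EnsembleResult:
    return sb.run_ensemble(11, ENSEMBLE_RUNS, seed=MASTER_SEED)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240817)


def random_sign_matrix(n: int, rng: np.random.Generator) -> sb.SignMatrix:
    s = rng.choice([-1, 1], size=(n, n))
    np.fill_diagonal(s, 0)
    return sb.SignMatrix(s)
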