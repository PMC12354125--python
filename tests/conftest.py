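import numpy as np
import pytest

from blockmc.models import BMCModel, ClusterAssignment


@pytest.fixture
def three_cluster_p():
    """A strongly separated 3-cluster transition matrix used throughout."""
    return np.array([[0.9, 0.1, 0.0], [0.0, 0.1, 0.9], [0.3, 0.7, 0.0]])


@pytest.fixture
def three_cluster_model(three_cluster_p):
    """The 3-cluster chain over 6 states, 2 per cluster."""
    return BMCModel(ClusterAssignment.balanced(6, 3), three_cluster_p)


def power_iteration_equilibrium(P, tol=1e-14, max_iter=200_000):
    """Independent stationary-distribution oracle: iterate pi <- pi P."""
    P = np.asarray(P, dtype=float)
    pi = np.full(P.shape[0], 1.0 / P.shape[0])
    for _ in range(max_iter):
        new = pi @ P
        new /= new.sum()
        if np.abs(new - pi).max() < tol:
            return new
        pi = new
    return pi
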