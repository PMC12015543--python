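import numpy as np
import pytest

from alngraph.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort_10k():
    """Default-spec cohort, large enough for marginal checks."""
    return generate_cohort(CohortSpec(n_patients=10000, seed=42))


@pytest.fixture(scope="session")
def null_cohort_20k():
    """Cohort with every feature-outcome effect set to zero."""
    spec = CohortSpec(
        n_patients=20000, seed=7,
        effect_log_odds={k: 0.0 for k in CohortSpec().effect_log_odds},
    )
    return generate_cohort(spec)


@pytest.fixture
def toy_graph():
    """A 6-node connected graph with random features and one-hot labels."""
    rng = np.random.default_rng(0)
    n, d = 6, 4
    A = np.zeros((n, n))
    for i, j in [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5), (1, 4)]:
        A[i, j] = A[j, i] = 1.0
    X = rng.normal(size=(n, d))
    labels = rng.integers(0, 2, n)
    Y = np.zeros((n, 2))
    Y[np.arange(n), labels] = 1.0
    return A, X, Y


def make_separable_graph(n_per_blob=30, d=4, sep=6.0, seed=0):
    """Two well-separated feature blobs with within-blob edges only.

    Linearly separable by construction, so any of the node classifiers
    should reach near-perfect training accuracy.
    """
    from alngraph.patient_graph import PatientGraph

    rng = np.random.default_rng(seed)
    n = 2 * n_per_blob
    X = rng.normal(size=(n, d))
    X[n_per_blob:, 0] += sep
    labels = np.r_[np.zeros(n_per_blob, int), np.ones(n_per_blob, int)]
    A = np.zeros((n, n))
    for blob in (range(n_per_blob), range(n_per_blob, n)):
        blob = list(blob)
        for idx in range(len(blob) - 1):
            i, j = blob[idx], blob[idx + 1]
            A[i, j] = A[j, i] = 1.0
    Y = np.zeros((n, 2))
    Y[np.arange(n), labels] = 1.0
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if A[i, j]]
    return PatientGraph(node_ids=tuple(f"N{i}" for i in range(n)), X=X, Y=Y,
                        edges=edges, A=A, threshold=0.0)
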