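import numpy as np
import pytest

from seroprofiler import panel as pn
from seroprofiler import synth


@pytest.fixture(scope="session")
def catalog():
    return pn.load_catalog()


@pytest.fixture(scope="session")
def default_cohort():
    """The seeded 76-patient study cohort (22 storage-protein-allergic)."""
    return synth.simulate_cohort(synth.CohortSimConfig(seed=11))


def separable_matrix(
    n_per_class: int = 20,
    n_clusters: int = 20,
    informative: tuple[int, int] = (3, 11),
    margin_sd: float = 4.0,
    seed: int = 0,
):
    """Two-class cluster matrix with informative features.

    The class centroids are separated by ``margin_sd`` noise standard
    deviations in the informative subspace (each informative cluster is
    shifted by margin/sqrt(k)); all other clusters are pure noise.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(0.0, 1.0, size=(n, n_clusters))
    y = np.array(["allergy"] * n_per_class + ["control"] * n_per_class)
    shift = margin_sd / np.sqrt(len(informative))
    for j in informative:
        X[:n_per_class, j] += shift
    return X + 10.0, y  # shift keeps intensities positive


def noise_matrix(n1: int = 22, n2: int = 54, n_clusters: int = 30, seed: int = 0):
    """Null matrix: log-normal intensities with no class effect."""
    rng = np.random.default_rng(seed)
    X = rng.lognormal(0.0, 0.5, size=(n1 + n2, n_clusters))
    y = np.array(["allergy"] * n1 + ["control"] * n2)
    return X, y
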