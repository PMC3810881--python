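import numpy as np
import pandas as pd
import pytest

from ecoregion_beta import (OccurrenceMatrix, ScenarioConfig, simulate)


@pytest.fixture
def tiny_occ() -> OccurrenceMatrix:
    """Three taxa, three ecoregions, hand-checkable."""
    inc = pd.DataFrame(
        [[True, True, False],
         [True, False, True],
         [False, True, True]],
        index=["t1", "t2", "t3"], columns=["A", "B", "C"])
    flags = pd.Series(["endemic", "nonendemic", "nonendemic"],
                      index=inc.index)
    rc = pd.Series({"t1": "baetic_only"}).reindex(inc.index)
    return OccurrenceMatrix(inc, flags, rc)


def random_occurrence(rng: np.random.Generator, n_taxa=30, n_eco=8,
                      p=0.35) -> OccurrenceMatrix:
    """Random occurrence matrix guaranteed free of empty rows/columns."""
    while True:
        inc = rng.random((n_taxa, n_eco)) < p
        if inc.any(axis=1).all() and inc.any(axis=0).all():
            break
    frame = pd.DataFrame(inc, index=[f"t{i}" for i in range(n_taxa)],
                         columns=[f"e{j}" for j in range(n_eco)])
    flags = pd.Series(np.where(rng.random(n_taxa) < 0.3, "endemic",
                               "nonendemic"), index=frame.index)
    rc = pd.Series("both", index=frame.index)
    return OccurrenceMatrix(frame, flags, rc)


def random_distance_matrix(rng: np.random.Generator, labels):
    """Euclidean distances between random planar points (valid metric)."""
    from scipy.spatial.distance import pdist
    from ecoregion_beta import DistanceMatrix
    pts = rng.random((len(labels), 2)) * 10
    return DistanceMatrix.from_condensed(pdist(pts), labels)


@pytest.fixture(scope="session")
def default_sim():
    """One shared default-scenario simulation (landscape, flora, truth)."""
    return simulate(ScenarioConfig(seed=42))


@pytest.fixture(scope="session")
def default_env(default_sim):
    from ecoregion_beta import build_env_table
    landscape, _, _ = default_sim
    return build_env_table(landscape.monthly)
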