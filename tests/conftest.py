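import numpy as np
import pandas as pd
import pytest

from lifespan_ec.io import ECMatrix, Parcellation, reference_parcellation


@pytest.fixture(scope="session")
def schaefer400():
    """Synthetic stand-in for the 400-region / 7-network parcellation."""
    return reference_parcellation()


@pytest.fixture
def toy_parcellation():
    """4 regions in 2 networks."""
    regions = ("A1", "A2", "B1", "B2")
    return Parcellation(
        region_ids=regions,
        network_of={"A1": "NA", "A2": "NA", "B1": "NB", "B2": "NB"},
        networks=("NA", "NB"),
    )


@pytest.fixture
def toy_parcellation_file(tmp_path, toy_parcellation):
    from lifespan_ec.io import write_parcellation

    path = tmp_path / "parcellation.tsv"
    write_parcellation(toy_parcellation, path)
    return path


@pytest.fixture
def random_ec():
    rng = np.random.default_rng(5)

    def make(n=8, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        values = r.normal(0, 0.3, (n, n))
        return ECMatrix(values=values, region_ids=tuple(f"R{i}" for i in range(n)))

    return make


@pytest.fixture
def metric_cohort():
    from lifespan_ec.synth import simulate_metric_cohort

    df, spec = simulate_metric_cohort(n_scans=300, seed=11)
    return df, spec
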