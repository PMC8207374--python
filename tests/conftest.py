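import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from zoicomp import Census, PlotSpec, SyntheticSpec, generate_census

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


def make_trees(rows, columns=("tree_id", "species", "x", "y",
                              "gbh_1", "status_1", "gbh_2", "status_2")):
    return pd.DataFrame(rows, columns=list(columns))


@pytest.fixture
def toy_plot():
    return PlotSpec(width=100.0, length=100.0, border=20.0,
                    census_dates=(0.0, 10.0))


@pytest.fixture
def toy_census(toy_plot):
    """Four trees, two species, two censuses."""
    trees = make_trees([
        ("a1", "spA", 50.0, 50.0, 20.0, "alive", 25.0, "alive"),
        ("a2", "spA", 52.0, 50.0, 40.0, "alive", 40.0, "dead"),
        ("b1", "spB", 30.0, 70.0, 15.0, "alive", 18.0, "alive"),
        ("b2", "spB", 10.0, 50.0, 90.0, "alive", 95.0, "alive"),
    ])
    return Census(trees=trees, plot=toy_plot)


@pytest.fixture(scope="session")
def small_forest():
    """A small clustered two-species census with known generative dynamics."""
    spec = SyntheticSpec(
        plot=PlotSpec(80.0, 80.0, 15.0, (0.0, 10.0)),
        counts=(220, 180, 150), cluster="thomas", cluster_sd=6.0,
        true_dd=0.0, spatial=True)
    return generate_census(spec, seed=42), spec
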