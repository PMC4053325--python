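import numpy as np
import pytest

from lekscape import synthetic
from lekscape.types import AnalysisConfig

EXTENT = (0.0, 0.0, 50_000.0, 50_000.0)


@pytest.fixture
def config():
    return AnalysisConfig(seed=7, n_permutations=49)


@pytest.fixture
def small_system():
    """A compact simulated landscape: 60 leks, two decades of pads, a decade
    of counts with a known step response on the 2-km 1-year-lag density."""
    truth = synthetic.SimulationTruth(
        coefficients={(2.0, 1): synthetic.step_field(25_000.0, -4.0, 0.0)},
        baseline=25.0,
        periodicity=(5.0, 6.0),
        noise="none",
    )
    leks = synthetic.generate_leks(60, EXTENT, seed=11)
    pads = synthetic.generate_wellpads(
        EXTENT, range(1992, 2012), base_intensity=0.01, seed=12
    )
    counted = synthetic.generate_counts(leks, pads, truth, range(2002, 2012), seed=13)
    return counted, pads, truth


def random_gwr_instance(rng, n, p=3):
    """A random small GWR problem (coords, X with intercept, y)."""
    coords = rng.uniform(0, 10_000, (n, 2))
    X = np.column_stack([np.ones(n), rng.normal(0, 1, (n, p - 1))])
    beta = rng.normal(0, 2, p)
    y = X @ beta + rng.normal(0, 1, n)
    return coords, X, y
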