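import numpy as np
import pandas as pd
import pytest

from funcresp.core_model import FRParams
from funcresp.synthetic_data import ExperimentDesign, generate_trials

ONE_GROUP = ("largemouth_bass", "small", "small")


def fixed_point_eaten(n0: float, a: float, h: float, t: float) -> float:
    """Independent oracle: damped iteration of Ne <- N0*(1 - exp(a*(Ne*h - T))).

    Averaging each update with the previous iterate keeps the map a
    contraction even when a*h*N0 > 1, and damping does not move the
    fixed point, so the iteration converges to the same root the
    Lambert-W form computes.
    """
    ne = 0.0
    for _ in range(500_000):
        ne_new = 0.5 * ne + 0.5 * n0 * (1.0 - np.exp(a * (ne * h - t)))
        if abs(ne_new - ne) < 1e-13:
            return ne_new
        ne = ne_new
    raise RuntimeError("fixed-point iteration did not converge")


@pytest.fixture
def one_group_design():
    """A single-group version of the cage experiment layout."""
    return ExperimentDesign(
        species=("largemouth_bass",), pred_sizes=("small",), prey_sizes=("small",)
    )


@pytest.fixture
def type2_trials(one_group_design):
    """Binomial trials from a type II truth (a=1, h=0.1), seed 7."""
    truths = {ONE_GROUP: FRParams(a=1.0, h=0.1)}
    return generate_trials(one_group_design, truths, seed=7)


@pytest.fixture
def toy_trials():
    """Two-trial toy dataset used against the dense grid-search oracle."""
    return pd.DataFrame({"n0": [8, 32], "ne": [4, 12], "t_hr": [1.0, 1.0]})
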