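import numpy as np
import pytest

from strainfate.dynamics import Community

# The study's pairwise selection coefficients of the focal strain vs each rival
# (focal advantage positive): cost vs its unmarked parent, larger costs vs two
# natural isolates, and an advantage vs the most divergent isolate.
PAIRWISE_S = {
    "L968": -0.05,
    "SPW23": -0.14,
    "R435": -0.18,
    "NCYC132": 0.18,
}

FOCAL = "L968mCherry"


def make_community(rivals, x0=0.5):
    return Community(
        strain_names=(FOCAL, *rivals),
        focal=FOCAL,
        selection_vs_focal={r: PAIRWISE_S[r] for r in rivals},
        initial_focal_frequency=x0,
    )


@pytest.fixture
def two_strain_community():
    return make_community(["NCYC132"])


@pytest.fixture
def five_strain_community():
    return make_community(list(PAIRWISE_S))


def closed_form_two_strain(x0: float, w: float, t: float) -> float:
    """Independent closed form for the two-strain model: the focal/rival
    ratio grows by 1/w per generation, so x(t) = x0 / (x0 + (1-x0) w^t)."""
    return x0 / (x0 + (1.0 - x0) * w**t)
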