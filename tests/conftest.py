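"""Shared fixtures.

The two case-study runs are expensive (each simulates the full net to its
steady state), so they are computed once per session and shared between the
validation and property tests.
"""

import pytest

from gradientpn import CASE_STUDIES, GradientParams, run_case_study
from gradientpn.pta import Marking, PTANet


@pytest.fixture(scope="session")
def dpp_result():
    return run_case_study("Dpp")


@pytest.fixture(scope="session")
def rescue_result():
    return run_case_study("Dpp-rescue")


@pytest.fixture(scope="session")
def dpp_params() -> GradientParams:
    return CASE_STUDIES["Dpp"]


@pytest.fixture
def linear_net() -> PTANet:
    """p --2--> t --1--> q, three-node chain used across the engine tests."""
    return PTANet(
        places={"p", "q"},
        transitions={"t"},
        weight={("p", "t"): 2, ("t", "q"): 1},
        initial_marking=Marking({"p": 5}),
    )
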