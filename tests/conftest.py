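"""Shared fixtures: the deterministic toy network and its two-cell variants."""

import logging

import pytest

from twocellfba import (
    H2Experiment,
    ToyScenario,
    compose_two_cell,
    make_expression,
    make_toy_model,
    regulate_two_cell,
    set_condition,
    to_irreversible_no_or,
)

logging.getLogger("twocellfba").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy():
    return make_toy_model()


@pytest.fixture(scope="session")
def diazo(toy):
    """Two-cell model, diazotrophic photoautotrophy, photon-limited budget."""
    return set_condition(compose_two_cell(toy), "diazotrophic_auto")


@pytest.fixture(scope="session")
def diazo_h2(toy):
    """Two-cell model under the regulated-photoautotrophic hydrogen preset
    (bicarbonate-limited, photons effectively unconstrained)."""
    return set_condition(
        compose_two_cell(toy), "diazotrophic_auto", hco3_uptake=1.0, photon_max=1000.0
    )


@pytest.fixture(scope="session")
def expanded_diazo(diazo):
    return to_irreversible_no_or(diazo)


@pytest.fixture(scope="session")
def bottleneck_expr(toy):
    return make_expression(toy, ToyScenario(name="psii_bottleneck"))


@pytest.fixture(scope="session")
def regulated(diazo, bottleneck_expr):
    """Regulated two-cell model with a binding PSII bottleneck (C = 0.01)."""
    return regulate_two_cell(diazo, bottleneck_expr, C=0.01)


@pytest.fixture(scope="session")
def het_exp():
    return H2Experiment()
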