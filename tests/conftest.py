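import numpy as np
import pytest

from sproutess.analogues import (
    Analogue,
    calibrated_model,
    candidum_analogue,
    ophrys_analogue,
    parviflorum_analogue,
)


@pytest.fixture(scope="session")
def parv() -> Analogue:
    return parviflorum_analogue()


@pytest.fixture(scope="session")
def cand() -> Analogue:
    return candidum_analogue()


@pytest.fixture(scope="session")
def oph() -> Analogue:
    return ophrys_analogue()


@pytest.fixture(scope="session")
def parv_model(parv):
    """Parviflorum-analogue model with calibrated density dependence."""
    return calibrated_model(parv)


@pytest.fixture(scope="session")
def cand_model(cand):
    return calibrated_model(cand)


@pytest.fixture(scope="session")
def oph_model(oph):
    return calibrated_model(oph)


@pytest.fixture(scope="session")
def calibrated_fixtures(parv, cand, oph, parv_model, cand_model, oph_model):
    return [(parv, parv_model), (cand, cand_model), (oph, oph_model)]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
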