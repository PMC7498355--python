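import numpy as np
import pytest

from aplbind import (
    PAPER_PARAMS_EU,
    BindingParameters,
    convert_scale,
    parse_config,
)


@pytest.fixture(scope="session")
def params_eu() -> BindingParameters:
    """Mean fitted in vivo parameter set on the expression-unit scale."""
    return PAPER_PARAMS_EU


@pytest.fixture(scope="session")
def params_nM(params_eu) -> BindingParameters:
    """Same parameters calibrated to the nM scale (d = 1.75)."""
    return convert_scale(params_eu, direction="to_nM")


@pytest.fixture(scope="session")
def wt_invivo():
    """Wild-type 11-site pR-pL lattice with both promoters active."""
    return parse_config("00111111100", pR_active=True, pL_active=True,
                        label="WT")


@pytest.fixture(scope="session")
def wt_invitro():
    """Wild-type 11-site lattice without RNAP species."""
    return parse_config("00111111100", label="WT-invitro")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
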