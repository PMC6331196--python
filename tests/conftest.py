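"""Shared fixtures: the canonical crossing panel and small simulations."""

import numpy as np
import pytest

from octadrive.cross_simulator import CrossConfig, build_cross
from octadrive.strains import ipo323, ipo323_deletion, ipo94269


@pytest.fixture(scope="session")
def parents():
    """The canonical cross: IPO323 (mat1-1) x IPO94269 (mat1-2)."""
    return ipo323(), ipo94269()


@pytest.fixture(scope="session")
def pairing(parents):
    return build_cross(*parents)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240913)


@pytest.fixture()
def mendelian_config(parents):
    """Zero-nuisance Mendelian cross of the canonical parents."""
    return CrossConfig(
        parent1=parents[0], parent2=parents[1], mechanism="mendelian",
        n_asci=10, seed=101,
    )


@pytest.fixture()
def drive_config(parents):
    return CrossConfig(
        parent1=parents[0], parent2=parents[1], mechanism="female_drive",
        n_asci=10, seed=202,
    )


@pytest.fixture()
def single_unpaired_config():
    """IPO323dchr20 x IPO94269: chr18 is the only unpaired chromosome."""
    return CrossConfig(
        parent1=ipo323_deletion("chr20"), parent2=ipo94269(),
        mechanism="mendelian", n_asci=100, seed=303,
    )
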