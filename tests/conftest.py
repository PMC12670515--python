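import random

import numpy as np
import pytest

from spinsq import config
from spinsq.oracle import FockSpaceSpec


@pytest.fixture(autouse=True)
def _reset_config():
    import dataclasses

    snapshot = dataclasses.asdict(config.settings)
    config.reset_stats()
    yield
    for key, value in snapshot.items():
        setattr(config.settings, key, value)


@pytest.fixture
def rng():
    return random.Random(20260922)


@pytest.fixture
def nprng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def spec2():
    """Two spatial orbitals, one occupied."""
    return FockSpaceSpec(n_spatial=2, n_occ=1)


@pytest.fixture(scope="session")
def spec3():
    """Three spatial orbitals, one occupied (two virtuals)."""
    return FockSpaceSpec(n_spatial=3, n_occ=1)


@pytest.fixture(scope="session")
def spec2_boson():
    return FockSpaceSpec(n_spatial=2, n_occ=1, boson_cutoff=2)


@pytest.fixture(scope="session")
def ccsd_report():
    """The CCSD derivation, shared across tests (deterministic)."""
    from spinsq.derivations import derive_cc_ground_state

    return derive_cc_ground_state(2)
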