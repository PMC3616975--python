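import warnings

import numpy as np
import pytest

from tetherdock.fixtures import make_helix_domain
from tetherdock.poses import seed_placement


@pytest.fixture(scope="session")
def static_domain():
    return make_helix_domain("ALKEFYRDILAVLKEA", chain="A", start_residue=1)


@pytest.fixture(scope="session")
def mobile_domain():
    return make_helix_domain("ILKDFYREILAVLKEA", chain="B", start_residue=101)


@pytest.fixture(scope="session")
def seed_pose(static_domain, mobile_domain):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return seed_placement(
            static_domain,
            mobile_domain,
            [("A", 8, ""), ("A", 9, "")],
            [("B", 108, ""), ("B", 109, "")],
            contact_gap=4.0,
        )


@pytest.fixture
def ca_selections(static_domain, mobile_domain):
    s = np.array([i for i, a in enumerate(static_domain.atoms) if a.name == "CA"])
    m = np.array([i for i, a in enumerate(mobile_domain.atoms) if a.name == "CA"])
    return s, m
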