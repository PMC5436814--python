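import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from amplimock.assays import mol16s_assay, sph16s_assay
from amplimock.communities import builtin_communities
from amplimock.refdb import synthetic_reference_database


@pytest.fixture(scope="session")
def mol16s():
    return mol16s_assay()


@pytest.fixture(scope="session")
def sph16s():
    return sph16s_assay()


@pytest.fixture(scope="session")
def refdb():
    return synthetic_reference_database(seed=0)


@pytest.fixture(scope="session")
def communities():
    return {c.community_id: c for c in builtin_communities()}
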