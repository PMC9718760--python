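import numpy as np
import pytest

from thiogag.conformer_sampler import EnsembleSpec, build_chain_ensemble
from thiogag.glycan_model import heparosan


@pytest.fixture(scope="session")
def hemi_a_ensemble():
    """Small hemi-A S-linked decasaccharide ensemble (shared, read-only)."""
    spec = EnsembleSpec(chain=heparosan(10, "hemi-A"), n_frames=60, seed=1234)
    return build_chain_ensemble(spec)


@pytest.fixture(scope="session")
def o_link_ensemble():
    spec = EnsembleSpec(chain=heparosan(10, "O"), n_frames=60, seed=1234)
    return build_chain_ensemble(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
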