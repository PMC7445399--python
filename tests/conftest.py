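import numpy as np
import pytest

from glycoarch import model, synth


@pytest.fixture
def disaccharide_tree():
    return model.parse_glycan("Gal(b1-3)GlcNAc")


@pytest.fixture
def disaccharide_ensemble(disaccharide_tree):
    """10-frame disaccharide built at phi=60, psi=-120 exactly."""
    ens, truth = synth.build_linked_ensemble(
        disaccharide_tree, {"phi": np.full(10, 60.0), "psi": np.full(10, -120.0)}
    )
    return ens, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
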