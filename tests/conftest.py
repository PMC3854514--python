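import numpy as np
import pytest

from tmexpo.fixtures import HelixSpec, bundle_helices, helix_bundle, synth_training_set


@pytest.fixture(scope="session")
def bundle4():
    """Four-helix bundle with distinct planted rotations (session cache)."""
    specs = [
        HelixSpec(n_residues=26, position=(10.0, 0.0), offset=30.0),
        HelixSpec(n_residues=21, position=(-10.0, 0.0), offset=200.0),
        HelixSpec(n_residues=18, position=(0.0, 10.0), offset=77.0),
        HelixSpec(n_residues=30, position=(0.0, -10.0), offset=311.0),
    ]
    structure, annotations, truths = helix_bundle(specs)
    helices = bundle_helices(structure, annotations)
    return structure, annotations, helices, truths


@pytest.fixture(scope="session")
def planted_dataset():
    """Noiseless 5-chain planted-signal training set (session cache)."""
    return synth_training_set(n_chains=5, residues_per_chain=36,
                              noise_sigma=0.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
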