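import numpy as np
import pytest

from allonet import (
    ENMSpec,
    build_toy_structure,
    make_toy_complex,
    sample_enm_ensemble,
)


@pytest.fixture(scope="session")
def helix_ensemble():
    """Small GNM-sampled helix ensemble with its analytic ground truth."""
    structure = build_toy_structure(20, "helix", seed=1)
    spec = ENMSpec(n_frames=2000, seed=3)
    return sample_enm_ensemble(structure, spec)


@pytest.fixture(scope="session")
def toy_complex():
    """Two-chain complex with 5 planted interface residues."""
    return make_toy_complex(30, 20, 5, seed=7, n_frames=200)


def make_iid_ensemble(n_residues: int, n_frames: int, sigma: float,
                      seed: int):
    """Extended-chain ensemble with isotropic i.i.d. Gaussian jitter."""
    structure = build_toy_structure(n_residues, "extended", seed=seed)
    ref = structure.reference_coordinates()
    rng = np.random.default_rng(seed)
    frames = ref[None] + sigma * rng.standard_normal(
        (n_frames,) + ref.shape)
    from allonet import ConformationalEnsemble

    return ConformationalEnsemble(reference=structure, frames=frames)
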