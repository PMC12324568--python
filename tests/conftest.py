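import numpy as np
import pytest

from stvae.synthetic import MorphologyParams, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A fast, fully populated synthetic tissue shared by read-only tests."""
    cfg = SynthConfig(
        n_cells=150, n_types=3, n_genes=12, abundance_skew=3.0,
        target_sparsity=0.75, image_size=512, crop_size=32,
        markers_per_type=3, marker_fold=20.0,
        morphology=[
            MorphologyParams(nucleus_radius=5, membrane_width=1.5),
            MorphologyParams(nucleus_radius=8, membrane_width=2.0,
                             eccentricity=0.4, polarized=True),
            MorphologyParams(nucleus_radius=11, membrane_width=3.0),
        ],
        seed=42,
    )
    return generate_dataset(cfg), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(0)
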