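import numpy as np
import pytest
from hypothesis import settings

import hsimoist as hm

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def wavelengths():
    return hm.default_wavelength_grid()


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless, scatter-free 6-piece scene (shared; treat as read-only)."""
    return hm.generate_scene(hm.SceneSpec(seed=7))


@pytest.fixture(scope="session")
def scattered_scene():
    """Scene with smooth multiplicative/additive scatter, no sensor noise."""
    return hm.generate_scene(hm.SceneSpec(seed=7, sigma_a=0.10, sigma_b=0.02))


@pytest.fixture(scope="session")
def clean_samples(clean_scene):
    """Segment spectra + exact reference moisture from the clean scene."""
    refl = hm.calibrate(clean_scene.raw, clean_scene.refs)
    data, seg_maps = hm.scene_to_samples(
        clean_scene, refl, reference_noise_sd=0.0,
        rng=np.random.default_rng(8),
    )
    return data, seg_maps, refl


def tiny_spectrum_set(n_blocks=4, n_per_block=5, n_bands=20, seed=0, y_rank=3):
    """Small labelled spectrum set with y linear in a few latent directions."""
    rs = np.random.default_rng(seed)
    n = n_blocks * n_per_block
    basis = rs.normal(size=(y_rank, n_bands))
    scores = rs.normal(size=(n, y_rank))
    X = scores @ basis + 0.01 * rs.normal(size=(n, n_bands)) + 1.0
    y = 55 + 4 * scores[:, 0] + 2 * scores[:, 1] + 0.05 * rs.normal(size=n)
    wl = np.linspace(400, 400 + 5 * (n_bands - 1), n_bands)
    ids = [f"b{b}:s{i:02d}" for b in range(n_blocks) for i in range(n_per_block)]
    blocks = [f"b{b}" for b in range(n_blocks) for _ in range(n_per_block)]
    return hm.SpectrumSet(X, wl, ids, blocks, np.clip(y, 1, 99))
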