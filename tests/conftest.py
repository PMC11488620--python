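import numpy as np
import pytest

from icapkit import synth
from icapkit.deconv import hrf_kernel


@pytest.fixture(scope="session")
def kernel_tr2():
    return hrf_kernel(2.0)


@pytest.fixture(scope="session")
def two_network_phantom(kernel_tr2):
    """Noise-free two-network session with known block trains."""
    rng = np.random.default_rng(42)
    atlas = synth.make_network_atlas(2, (6, 6, 6), overlap_frac=0.0, seed=1)
    trains = np.zeros((2, 80))
    trains[0, 15:25] = 1.0
    trains[0, 50:60] = 1.0
    trains[1, 30:42] = 1.0
    sess = synth.simulate_bold(atlas, trains, tr=2.0, noise_sd=0.0, rng=rng)
    return atlas, trains, sess


@pytest.fixture(scope="session")
def planted_frames():
    """Three orthogonal spatial patterns plus small noise, known labels."""
    rng = np.random.default_rng(7)
    n_vox = 90
    patterns = np.zeros((3, n_vox))
    for k in range(3):
        patterns[k, k * 30 : (k + 1) * 30] = 1.0
    labels = np.repeat([0, 1, 2], 40)
    signs = rng.choice([-1.0, 1.0], size=len(labels))
    frames = signs[:, None] * patterns[labels] + rng.normal(0, 0.15, (len(labels), n_vox))
    return frames, labels
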