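import warnings

import pytest

from civa.simulate import ImageSimConfig, sim_image_stack

# scikit-image 0.26 deprecation chatter from morphology helpers is not ours
warnings.filterwarnings("ignore", category=FutureWarning, module="civa.quantify")


@pytest.fixture(scope="session")
def clean_stack():
    """A small noise-free rendered acquisition with truth (shared, read-only)."""
    cfg = ImageSimConfig(seed=3, n_frames=4)
    stack, truth = sim_image_stack(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def noisy_stack():
    """SNR-10 acquisition with Poisson + read noise."""
    cfg = ImageSimConfig(seed=7, snr=10.0, poisson=True, n_frames=3)
    stack, truth = sim_image_stack(cfg)
    return cfg, stack, truth
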