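import numpy as np
import pytest

from fibralign import FiberFieldParams, PipelineConfig, generate_fiber_image


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def aligned_field():
    """Strongly aligned fiber field (κ=100, μ=45°) with ground truth."""
    params = FiberFieldParams(image_size=256, n_fibers=150,
                              mean_orientation=np.pi / 4,
                              concentration=100.0, seed=7)
    image, truth = generate_fiber_image(params)
    return params, image, truth


@pytest.fixture(scope="session")
def isotropic_field():
    """Isotropic fiber field (κ=0) with ground truth."""
    params = FiberFieldParams(image_size=256, n_fibers=300,
                              concentration=0.0, seed=3)
    image, truth = generate_fiber_image(params)
    return params, image, truth
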