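import numpy as np
import pytest

from symatlas.phantom import JitterSpec, PhantomSpec, generate_head_phantom


def dice(a, b) -> float:
    a = np.asarray(a.data if hasattr(a, "data") else a) > 0.5
    b = np.asarray(b.data if hasattr(b, "data") else b) > 0.5
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def phantom_2mm():
    """Symmetric, noise- and bias-free head at 2 mm (fast unit-test grid)."""
    spec = PhantomSpec(grid_mm=2.0)
    return generate_head_phantom(spec)


@pytest.fixture(scope="session")
def phantom_2mm_asym():
    """Left hemisphere scaled by 1.05, otherwise clean."""
    spec = PhantomSpec(grid_mm=2.0, left_scale=1.05)
    return generate_head_phantom(spec)


@pytest.fixture(scope="session")
def small_jitter():
    return JitterSpec(translation_mm=2.0, rotation_deg=3.0, scale=0.03,
                      shear=0.01, warp_mm=0.5)
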