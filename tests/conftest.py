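import numpy as np
import pytest

from ubmseg import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom (bias 0.3, noise 0.02) shared across tests."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, bias-free phantom: observed image equals the true image."""
    from ubmseg import BiasParams

    spec = PhantomSpec(
        bias_params=BiasParams(amplitude=0.0), noise_sigma=0.0, seed=7
    )
    return generate_phantom(spec)


def rasterize_ellipse(shape, center, semi_axes, rotation=0.0):
    """Pixel-center-enumeration oracle for ellipse rasterisation."""
    h, w = shape
    cy, cx = center
    ax, ay = semi_axes
    mask = np.zeros(shape, dtype=bool)
    ct, st = np.cos(rotation), np.sin(rotation)
    for r in range(h):
        for c in range(w):
            dx, dy = c - cx, r - cy
            u = ct * dx + st * dy
            v = -st * dx + ct * dy
            if (u / ax) ** 2 + (v / ay) ** 2 <= 1.0:
                mask[r, c] = True
    return mask
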