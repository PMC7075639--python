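import numpy as np
import pytest

from zlinekit import GrayImage, PhantomSpec, make_tissue_phantom
from zlinekit.pipeline import analyze_image


@pytest.fixture(scope="session")
def ordered_phantom():
    """Fully ordered two-channel phantom (no off-target staining)."""
    spec = PhantomSpec(offtarget_fraction=0.0, seed=7)
    actin, actinin, zline_truth, offtarget_truth = make_tissue_phantom(spec)
    return spec, actin, actinin, zline_truth, offtarget_truth


@pytest.fixture(scope="session")
def mixed_phantom():
    """Phantom with half of the α-actinin structure drawn as off-target."""
    spec = PhantomSpec(offtarget_fraction=0.5, seed=7)
    actin, actinin, zline_truth, offtarget_truth = make_tissue_phantom(spec)
    return spec, actin, actinin, zline_truth, offtarget_truth


@pytest.fixture(scope="session")
def ordered_phantom_result(ordered_phantom):
    _, actin, actinin, _, _ = ordered_phantom
    return analyze_image(actinin, actin, image_id="ordered")


@pytest.fixture(scope="session")
def mixed_phantom_result(mixed_phantom):
    _, actin, actinin, _, _ = mixed_phantom
    return analyze_image(actinin, actin, image_id="mixed")


@pytest.fixture
def vertical_stripes():
    """Vertical bright stripes: ridge direction is vertical (θ = π/2)."""
    x = np.arange(64)
    pattern = 0.5 + 0.5 * np.sin(2 * np.pi * x / 8.0)
    return GrayImage(np.tile(pattern, (64, 1)))
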