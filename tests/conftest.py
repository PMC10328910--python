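import numpy as np
import pytest

from nucleoprog import FeatureManifest, NucleusPhenotype, generate_roi_image


@pytest.fixture(scope="session")
def manifest():
    return FeatureManifest()


@pytest.fixture(scope="session")
def small_roi():
    """A deterministic 20-nucleus ROI image."""
    return generate_roi_image(NucleusPhenotype(), n_nuclei=20, image_size=128, seed=7)


def disk_image(radius, center=None, shape=None, intensity_value=100):
    """Labeled disk mask plus constant intensity, for shape/radial checks."""
    shape = shape or (2 * radius + 5, 2 * radius + 5)
    center = center or (shape[0] // 2, shape[1] // 2)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    labels = mask.astype(np.int32)
    intensity = np.where(mask, intensity_value, 0).astype(np.uint8)
    return intensity, labels
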