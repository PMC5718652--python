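import numpy as np
import pytest

import portalreg as pr
from portalreg import synthetic as syn

SMALL = dict(shape=(128, 128), pixel_spacing_mm=1.0)


@pytest.fixture(scope="session")
def chest_scene():
    return pr.make_scene("chest", seed=1)


@pytest.fixture(scope="session")
def pelvis_scene():
    return pr.make_scene("pelvis", seed=1)


@pytest.fixture(scope="session")
def small_drr(chest_scene):
    return syn.render_drr(chest_scene, **SMALL)


def make_portal(scene, offset, contrast=1.0, noise_sigma=0.0, seed=7, **render_kw):
    case = syn.SyntheticCase(
        "t", tuple(offset), contrast=contrast, noise_sigma=noise_sigma, seed=seed
    )
    kw = {**SMALL, **render_kw}
    return syn.render_portal(scene, case, **kw)


@pytest.fixture(scope="session")
def smooth_image():
    """A smooth beam-framed test image (no burned-in graphics)."""
    frame = pr.BeamFrame((63.5, 63.5), 1.0)
    rows, cols = np.mgrid[0:128, 0:128].astype(float)
    x = (cols - 63.5) * 1.0
    y = -(rows - 63.5) * 1.0
    img = 500.0 + 300.0 * np.exp(-((x - 10) ** 2 + (y + 5) ** 2) / (2 * 30.0**2)) + 2.0 * np.sin(
        x / 9.0
    ) * np.cos(y / 11.0) * 40.0
    return pr.ImageGrid(img, (1.0, 1.0), frame)
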