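import numpy as np
import pytest

from ccshape.imaging_io import CCMask
from ccshape.phantom import AnnulusSectorSpec, make_annulus_sector, make_cc_phantom


@pytest.fixture(scope="session")
def quarter_sector():
    """Annulus sector r=20/30 mm, quarter turn, 0.5 mm grid — the
    canonical closed-form oracle."""
    spec = AnnulusSectorSpec(r_inner=20, r_outer=30, angle=np.pi / 2,
                             center=(64, 64), pixel_spacing=0.5)
    mask, truth = make_annulus_sector(spec, (256, 256))
    return spec, mask, truth


@pytest.fixture(scope="session")
def normal_phantom():
    return make_cc_phantom(seed=42, label="normal")


@pytest.fixture()
def rect_mask():
    """40 x 4 px horizontal bar at 1 mm spacing."""
    lab = np.zeros((24, 60), dtype=np.uint8)
    lab[10:14, 10:50] = 1
    return CCMask(lab, pixel_spacing=(1.0, 1.0))


def separable_features(n_per_class=40, gap=6.0, n_features=8, seed=0):
    """Two Gaussian clusters separated well beyond their spread."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n_per_class, n_features))
    b = rng.normal(gap, 1.0, (n_per_class, n_features))
    x = np.vstack([a, b])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return x, y
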