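import numpy as np
import pytest

from radiorobust.synthetic import make_tda_phantom
from radiorobust.types import MODALITIES, SlicePatch


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def textured_patch():
    """A 64x64 disk patch with smooth random texture in all channels."""
    sp = make_tda_phantom("disk", size=64)
    r = np.random.default_rng(7)
    import scipy.ndimage as ndi

    for m in MODALITIES:
        field = ndi.gaussian_filter(r.standard_normal((64, 64)), 2.0)
        sp.channels[m] = 1.0 + field + 0.05 * r.standard_normal((64, 64))
    return sp


@pytest.fixture()
def random_patch142():
    """Full-size 142x142 patch with pure white-noise channels."""
    r = np.random.default_rng(99)
    mask = np.zeros((142, 142), bool)
    mask[20:120, 25:115] = True
    return SlicePatch(
        patient_id="R",
        slice_index=0,
        channels={m: r.standard_normal((142, 142)) for m in MODALITIES},
        mask=mask,
        label=0,
    )
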