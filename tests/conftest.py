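import numpy as np
import pytest

from petseg.phantom import Lesion, PhantomSpec, generate
from petseg.suv_io import GridRef, PETVolume, ROISet


@pytest.fixture
def small_volume():
    """Seeded random 8x8x8 SUV volume at 2 mm isotropic spacing."""
    rng = np.random.default_rng(42)
    return PETVolume(rng.uniform(0.0, 10.0, size=(8, 8, 8)), (2.0, 2.0, 2.0))


@pytest.fixture
def grid_8():
    return GridRef((8, 8, 8), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))


@pytest.fixture
def clean_phantom():
    """Single-sphere phantom with no blur and no noise (two-valued image)."""
    spec = PhantomSpec(
        lesions=[Lesion((64.0, 64.0, 64.0), (12.0, 12.0, 12.0), 5.0)],
        psf_fwhm_mm=0.0,
        noise_sd=0.0,
    )
    return generate(spec)


@pytest.fixture
def blurred_phantom():
    """Two-sphere phantom with 7 mm FWHM blur and 10%-of-background noise."""
    spec = PhantomSpec(
        lesions=[
            Lesion((40.0, 40.0, 40.0), (11.0, 11.0, 11.0), 6.0),
            Lesion((90.0, 90.0, 90.0), (8.0, 9.0, 10.0), 8.0),
        ],
        psf_fwhm_mm=7.0,
        noise_sd=0.1,
        seed=11,
    )
    return generate(spec)


def make_rois(mask_or_labels, grid):
    labels = np.asarray(mask_or_labels)
    if labels.dtype == bool:
        labels = labels.astype(np.int32)
    return ROISet(labels, grid)
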