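import numpy as np
import pytest

from pollengerm.cohorts import kinetics_cohort, vesicle_peak_cohort
from pollengerm.growth_models import GrainGeometry
from pollengerm.synthetic_microscopy import AcquisitionSpec


@pytest.fixture(scope="session")
def fast_acq() -> AcquisitionSpec:
    """Small, few-slice acquisition for unit tests that need rendered images."""
    return AcquisitionSpec(
        pixel_size=0.5,
        frame_shape=(96, 192),
        origin=(0.0, 0.0),
        n_slices=5,
    )


@pytest.fixture(scope="session")
def grain() -> GrainGeometry:
    # off-grid center and slightly tilted axis avoid degenerate alignment of
    # straight tube edges with pixel-center rows
    return GrainGeometry(center=(24.3, 24.2), germination_angle=0.05)


@pytest.fixture(scope="session")
def rendered_tube(fast_acq, grain):
    """One rendered slow-then-fast tube with ground truth (cytoplasm only)."""
    from pollengerm.cohorts import build_tube_schedule
    from pollengerm.synthetic_microscopy import render_timelapse

    tube = build_tube_schedule(grain, 16, 3, 16.7, 31.0)
    tl, gt = render_timelapse(grain, tube.schedule, ["cytoplasm"], fast_acq, seed=7)
    return tl, gt


@pytest.fixture(scope="session")
def small_peak_cohort():
    """Ten tubes, eight with a site-concordant pre-germination vesicle peak."""
    return list(vesicle_peak_cohort(n_tubes=10, n_concordant=8, seed=3))


def random_blob(rng: np.random.Generator, shape=(64, 64)) -> np.ndarray:
    """A random connected blob mask (thresholded smoothed noise)."""
    from scipy.ndimage import gaussian_filter
    from skimage.measure import label as cc_label

    img = gaussian_filter(rng.normal(size=shape), sigma=rng.uniform(2, 6))
    mask = img > np.quantile(img, rng.uniform(0.7, 0.95))
    labels = cc_label(mask)
    if labels.max() == 0:
        mask = np.zeros(shape, bool)
        mask[28:36, 25:39] = True
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))
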