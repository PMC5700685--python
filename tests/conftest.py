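import dataclasses

import numpy as np
import pytest

from nfquant.pipeline import measure_slide
from nfquant.synthetic import CalibrationProfile, generate_slide


@pytest.fixture(scope="session")
def sparse_profile() -> CalibrationProfile:
    """Low-density calibration that fits comfortably on small test images."""
    return CalibrationProfile(means=(8.0, 6.0, 5.0, 6.0), sds=(2.0, 2.0, 1.5, 2.0))


@pytest.fixture(scope="session")
def small_slide(sparse_profile):
    """One 512x512 synthetic specimen with annotation and ground truth."""
    return generate_slide(sparse_profile, width=512, height=512, seed=20170)


@pytest.fixture(scope="session")
def measured_small_slide(small_slide):
    slide, annotation, _ = small_slide
    return measure_slide(slide, annotation)


def zero_profile() -> CalibrationProfile:
    """Degenerate calibration: no objects at all."""
    return CalibrationProfile(means=(0.0,) * 4, sds=(0.0,) * 4)
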