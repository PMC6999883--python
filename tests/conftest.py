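import numpy as np
import pytest

from velquant.synthetic import (
    ClassGaussianSpec,
    CohortConfig,
    ImageSceneSpec,
)
from velquant.roi import CircleROI


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def well_separated_specs():
    """Three classes far apart in feature space; any sane classifier is
    near-perfect on a draw from these."""
    return [
        ClassGaussianSpec("N", (1.3, 0.2), ((0.003, 0.0), (0.0, 0.003))),
        ClassGaussianSpec("M", (0.6, 0.6), ((0.003, 0.0), (0.0, 0.003))),
        ClassGaussianSpec("PM", (1.0, 1.1), ((0.003, 0.0), (0.0, 0.003))),
    ]


@pytest.fixture
def heteroscedastic_specs():
    """Overlapping means with strongly class-dependent covariances: the
    regime where the quadratic rule should beat the linear one."""
    return [
        ClassGaussianSpec("N", (1.0, 0.5), ((0.01, 0.0), (0.0, 0.01))),
        ClassGaussianSpec("M", (1.1, 0.6), ((0.25, 0.0), (0.0, 0.25))),
    ]


def make_scene(
    label="N",
    pattern="FVR",
    shift=50.0,
    het=0.0,
    seed=7,
    size=(64, 64),
    confounders=(),
    **kwargs,
):
    return ImageSceneSpec(
        subsite="tongue",
        class_label=label,
        image_size=size,
        roi=CircleROI(32.0, 32.0, 14.0),
        pattern=pattern,
        roi_intensity_shift=shift,
        heterogeneity_sd=het,
        confounders=tuple(confounders),
        seed=seed,
        **kwargs,
    )


@pytest.fixture
def tiny_cohort_config():
    return CohortConfig(
        counts={"tongue": {"N": 6, "PM": 6, "M": 6}},
        image_size=(64, 64),
        roi_radius_range=(10.0, 14.0),
    )
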