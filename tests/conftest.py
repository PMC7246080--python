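import numpy as np
import pytest

from ctvshift import (Contour, GeneratorParams, SagittalAnatomy,
                      extract_cohort_features, simulate_cohort)


def rectangle(a_lo, a_hi, s_lo, s_hi) -> Contour:
    return Contour([(a_lo, s_lo), (a_hi, s_lo), (a_hi, s_hi), (a_lo, s_hi)])


@pytest.fixture
def rectangle_anatomy() -> SagittalAnatomy:
    """Axis-aligned organs with closed-form distances.

    Bone corners put landmark S at (0, 0) and I at (2, -40); against the
    rectum a in [-45, -30], s in [-60, 10] and bladder a in [-10, 30],
    s in [5, 45] the seven distances have hand-computable values.
    """
    return SagittalAnatomy(
        bladder=rectangle(-10, 30, 5, 45),
        rectum=rectangle(-45, -30, -60, 10),
        prostate=rectangle(-25, -5, -35, -5),
        ctv=rectangle(-27, -3, -37, 3),
        bone=Contour([(0, 0), (10, 5), (15, -35), (2, -40)]),
    )


@pytest.fixture(scope="session")
def default_params() -> GeneratorParams:
    return GeneratorParams()


@pytest.fixture(scope="session")
def small_cohort(default_params):
    return simulate_cohort(default_params, 4, 6, seed=101)


@pytest.fixture(scope="session")
def small_features(default_params, small_cohort):
    return extract_cohort_features(small_cohort, default_params.click_noise_sd,
                                   seed=102,
                                   cop_click_noise_sd=default_params.cop_click_noise_sd)
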