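import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from psrquant import (
    CohortDesign,
    SegmentationConfig,
    SlideGenParams,
    make_cohort,
    make_slide,
    segment_slide,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    return SegmentationConfig()


@pytest.fixture(scope="session")
def default_slide():
    """The standard fixture: 1024x1024 at 20X, septal pattern, 10% CPA."""
    return make_slide(SlideGenParams(width_px=1024, height_px=1024,
                                     target_cpa=10.0, seed=52))


@pytest.fixture(scope="session")
def default_result(default_slide, cfg):
    return segment_slide(default_slide.as_wsi(), cfg)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """2 groups x 3 animals x 3 sections of small slides, seed-fixed."""
    out = tmp_path_factory.mktemp("cohort")
    design = CohortDesign(
        groups=(("control", 0, 3), ("week18", 18, 3)),
        slide_width_px=512, slide_height_px=512, seed=11,
    )
    bundle = make_cohort(design, str(out))
    bundle["design"] = design
    return bundle
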