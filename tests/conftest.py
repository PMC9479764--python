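import dataclasses

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from neocorr.synthetic_cohort import (  # noqa: E402
    CohortParams,
    SlidePatternParams,
    VariantParams,
    generate_patient_cohort,
)


def small_slide_params(**overrides) -> SlidePatternParams:
    """A fast slide: 0.8 x 0.8 mm field, two nests, default densities."""
    base = dict(
        field_width_um=800.0,
        field_height_um=800.0,
        tumor_nest_count=2,
        nest_radius_mean_um=180.0,
        nest_radius_sd_um=40.0,
        tumor_cell_density=800.0,
    )
    base.update(overrides)
    return SlidePatternParams(**base)


def tiny_cohort_params(**overrides) -> CohortParams:
    """A 6-patient cohort with shrunken slides and variant load."""

    def shrink(p: SlidePatternParams) -> SlidePatternParams:
        return dataclasses.replace(
            p, field_width_um=800.0, field_height_um=800.0,
            tumor_nest_count=2, nest_radius_mean_um=180.0, nest_radius_sd_um=40.0,
            tumor_cell_density=800.0,
        )

    defaults = CohortParams()
    base = dict(
        n_patients=6,
        responder_fraction=0.5,
        responder_pre=shrink(defaults.responder_pre),
        responder_post=shrink(defaults.responder_post),
        nonresponder_pre=shrink(defaults.nonresponder_pre),
        nonresponder_post=shrink(defaults.nonresponder_post),
        variants=VariantParams(n_genes=20, mutation_count_mean=12.0),
        seed=11,
    )
    base.update(overrides)
    return CohortParams(**base)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_patient_cohort(tiny_cohort_params())
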