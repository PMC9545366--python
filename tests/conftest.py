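import numpy as np
import pytest

from hipshape.schema import DEFAULT_SCHEMA
from hipshape.simulate import (GenerativeShapeSpec, OutcomeModelSpec,
                               make_template, sample_cohort)


@pytest.fixture(scope="session")
def schema():
    return DEFAULT_SCHEMA


@pytest.fixture(scope="session")
def template():
    return make_template()


@pytest.fixture(scope="session")
def shape_spec():
    """Default generative spec (noise 0.5 mm)."""
    return GenerativeShapeSpec.default()


@pytest.fixture(scope="session")
def noise_free_spec():
    return GenerativeShapeSpec.default(point_noise_sd=0.0)


@pytest.fixture(scope="session")
def outcome_spec():
    return OutcomeModelSpec.default()


@pytest.fixture(scope="session")
def small_cohort(shape_spec, outcome_spec):
    """One modest cohort shared across read-only tests."""
    return sample_cohort(shape_spec, outcome_spec, n=400, seed=42)


def deformed_configs(spec, scores, noise_sd=0.0, seed=0):
    """Configurations deformed along the spec's modes with given raw scores."""
    from hipshape.schema import LandmarkConfiguration
    rng = np.random.default_rng(seed)
    tmpl = spec.template.points
    fields = np.asarray(spec.modes)
    out = []
    for i, z in enumerate(np.atleast_2d(scores)):
        pts = tmpl + np.tensordot(z, fields[: len(z)], axes=1)
        if noise_sd:
            pts = pts + rng.normal(0, noise_sd, pts.shape)
        out.append(LandmarkConfiguration(f"D{i:04d}", pts))
    return out
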