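import numpy as np
import pytest

from svdmap.synthetic import LesionSpec, TemplateSpec, make_subject, make_template


@pytest.fixture(scope="session")
def template_spec():
    return TemplateSpec()


@pytest.fixture(scope="session")
def template_and_atlas(template_spec):
    return make_template(template_spec)


@pytest.fixture(scope="session")
def template(template_and_atlas):
    return template_and_atlas[0]


@pytest.fixture(scope="session")
def atlas(template_and_atlas):
    return template_and_atlas[1]


@pytest.fixture(scope="session")
def subject(template_and_atlas, template_spec):
    """One default synthetic subject used across segmentation tests."""
    template, atlas = template_and_atlas
    return make_subject(
        template, atlas, LesionSpec(), seed=11, template_spec=template_spec, subject_id="sub-011"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
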