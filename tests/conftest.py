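import pytest

from studytemplates import (
    SynthConfig,
    TemplateSpec,
    bridg_like_fixture,
    build_template,
    generate,
    load_model_from_texts,
    measurement_use_case_spec,
    normalize,
)


@pytest.fixture(scope="session")
def bridg_model():
    domain, datatypes = bridg_like_fixture()
    return load_model_from_texts(domain, datatypes)


@pytest.fixture(scope="session")
def bridg_normalized(bridg_model):
    return normalize(bridg_model)


@pytest.fixture(scope="session")
def measurement_template(bridg_normalized):
    spec = TemplateSpec.from_dict(measurement_use_case_spec())
    return build_template(bridg_normalized, spec)


@pytest.fixture
def synth_normalized():
    """Factory: generate a synthetic model, load and normalize it."""

    def make(**kwargs):
        cfg = SynthConfig(**kwargs)
        sm = generate(cfg)
        model = load_model_from_texts(sm.domain_ttl, sm.datatype_ttl)
        return sm, model, normalize(model)

    return make


@pytest.fixture
def fixture_files(tmp_path):
    """The example model written to disk, for file-based entry points."""
    domain, datatypes = bridg_like_fixture()
    d = tmp_path / "domain.ttl"
    t = tmp_path / "datatypes.ttl"
    d.write_text(domain)
    t.write_text(datatypes)
    return d, t
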