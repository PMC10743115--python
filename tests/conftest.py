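import pytest

from astigvec.simulate import GeneratorConfig, generate_cohort, identity_config


@pytest.fixture(scope="session")
def default_cohort():
    """The standard 95-eye synthetic cohort (default study conditions)."""
    return generate_cohort(GeneratorConfig(n_eyes=95, seed=42))


@pytest.fixture(scope="session")
def identity_cohort():
    """Noise-free cohort where every modality equals the refraction exactly."""
    return generate_cohort(identity_config(n_eyes=40, seed=7))


@pytest.fixture()
def cohort_csv(tmp_path, default_cohort):
    from astigvec.cohort import write_cohort

    path = tmp_path / "cohort.csv"
    write_cohort(default_cohort, path)
    return path
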