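import pytest
from hypothesis import settings

from thrombotext.lexicon import bundled_lexicon
from thrombotext.synthetic import GeneratorConfig, generate_corpus

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lexicon():
    return bundled_lexicon()


@pytest.fixture(scope="session")
def small_corpus():
    """120 noise-free synthetic reports with gold annotations and labels."""
    return generate_corpus(GeneratorConfig(n_reports=120, seed=7))


@pytest.fixture(scope="session")
def study_corpus():
    """600 noise-free reports at the study prevalences (shared, read-only)."""
    return generate_corpus(GeneratorConfig(n_reports=600, seed=42))
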