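import pytest

from carestrat import default_concept_lexicon, default_spec, generate_corpus
from carestrat.labels import ClassLabel
from carestrat.synthetic import CorpusSpec, spec_with


@pytest.fixture(scope="session")
def lexicon():
    return default_concept_lexicon()


@pytest.fixture(scope="session")
def default_corpus():
    """The full 1,576-record default synthetic corpus (seed 42)."""
    return generate_corpus(default_spec())


@pytest.fixture(scope="session")
def small_spec():
    """A reduced corpus spec for fast end-to-end tests (same class ratios)."""
    return spec_with(
        default_spec(seed=7),
        class_counts={
            ClassLabel.ENV: 120,
            ClassLabel.SELF: 60,
            ClassLabel.PREF: 40,
            ClassLabel.COMP: 40,
            ClassLabel.NONSTRAT: 40,
        },
    )


@pytest.fixture(scope="session")
def small_corpus(small_spec: CorpusSpec):
    return generate_corpus(small_spec)
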