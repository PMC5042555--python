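import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from litclf import (
    Corpus,
    Document,
    GeneratorConfig,
    default_class_specs,
    generate_corpus,
)

MEDLINE_RECORD = """\
PMID- 1
TI  - Breast cancer study.
AB  - We studied X.

PMID- 2
TI  - Lung cancer incidence in a cohort
      followed for ten years.
AB  - Incidence was measured.
"""


@pytest.fixture
def tiny_corpus():
    return Corpus(
        [
            Document("1", "the incidence of breast cancer", "breast"),
            Document("2", "lung cancer screening with, commas", "lung"),
            Document("3", "prostate specific antigen", "prostate"),
        ]
    )


@pytest.fixture(scope="session")
def study_corpus():
    """The 3-class synthetic study corpus: 600 documents, signal 0.5, seed 1."""
    return generate_corpus(
        default_class_specs(n_classes=3, n_per_class=200, signal=0.5),
        GeneratorConfig(seed=1),
    )


@pytest.fixture(scope="session")
def small_corpus():
    """A quick 3-class corpus for pipeline-level unit tests."""
    return generate_corpus(
        default_class_specs(n_classes=3, n_per_class=30, signal=0.5),
        GeneratorConfig(seed=3, mean_length=60.0),
    )
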