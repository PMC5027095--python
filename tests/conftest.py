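import pytest

from plurisig import (
    GeneAnnotationRecord,
    default_config,
    generate_study,
    study_feature_matrix,
)


@pytest.fixture
def tiny_annotation():
    return [
        GeneAnnotationRecord("gA", "chr1", 1000, "+"),
        GeneAnnotationRecord("gB", "chr1", 500_000, "-"),
        GeneAnnotationRecord("gC", "chr2", 2000, "+"),
    ]


@pytest.fixture(scope="session")
def small_study():
    """A small planted-signal study shared by selection/ensemble tests."""
    cfg = default_config(n_genes=300, n_positive=40, seed=7)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_study):
    return study_feature_matrix(small_study)


@pytest.fixture(scope="session")
def small_matrix_raw(small_study):
    return study_feature_matrix(small_study, normalize=False)
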