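import numpy as np
import pytest

from hglink import (
    DiseaseOntology,
    HglConfig,
    SimilarityMatrix,
    SyntheticSpec,
    build_training_set,
    fused_matrices,
    generate,
    semantic_similarity,
)


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec()


@pytest.fixture(scope="session")
def synthetic_data(default_spec):
    """Default synthetic dataset: (AssociationMatrix, base SM, ontology)."""
    return generate(default_spec)


@pytest.fixture(scope="session")
def fused(synthetic_data):
    """Fused SM/SD matrices for the default synthetic dataset."""
    am, base_sm, onto = synthetic_data
    sd_sem = semantic_similarity(onto, am.disease_ids).SD_sem
    return fused_matrices(am, base_sm, sd_sem)


@pytest.fixture(scope="session")
def training_set(synthetic_data, fused):
    am, _, _ = synthetic_data
    SM, SD = fused
    return build_training_set(am, SM, SD, 0)


@pytest.fixture
def tiny_ontology():
    """d1 -> d2: the two-term chain used in the worked similarity examples."""
    return DiseaseOntology({"d1", "d2"}, {("d1", "d2")}, ["d1", "d2"])


def random_dag(rng, n_terms, n_diseases=None):
    """Random layered DAG over n_terms: each non-root term gets 1-2 parents
    among earlier terms; a random subset is the diseases of interest."""
    terms = [f"t{i}" for i in range(n_terms)]
    edges = set()
    for i in range(1, n_terms):
        n_par = int(rng.integers(1, min(3, i + 1)))
        for p in rng.choice(i, size=n_par, replace=False):
            edges.add((terms[i], terms[int(p)]))
    if n_diseases is None:
        n_diseases = int(rng.integers(1, n_terms + 1))
    dis = [terms[i] for i in sorted(rng.choice(n_terms, size=n_diseases, replace=False))]
    return DiseaseOntology(set(terms), edges, dis)
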