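import numpy as np
import pytest

from redrug.kg_io import EntityRef, Triple
from redrug.synth import SyntheticKGSpec, SyntheticMatrixSpec, gen_kg, gen_score_matrix


def make_triple(head: str, rel: str, tail: str) -> Triple:
    return Triple(EntityRef.parse(head), rel, EntityRef.parse(tail))


@pytest.fixture(scope="session")
def small_kg():
    """Default small synthetic knowledge graph (seeded)."""
    return gen_kg(SyntheticKGSpec(seed=1))


@pytest.fixture(scope="session")
def small_matrix():
    """A compact planted score matrix for aggregation tests."""
    return gen_score_matrix(
        SyntheticMatrixSpec(
            n_diseases=12, n_drugs=200, n_clusters=3, n_hits=8, cluster_effect=0.8, seed=3
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def triples_file(tmp_path):
    """A 5-line DRKG-dialect TSV with one malformed line."""
    lines = [
        "Compound::DB00001\tGNBR::T::Compound:Disease\tDisease::MESH:D003141",
        "Compound::DB00001\tDRUGBANK::target::Compound:Gene\tGene::1234",
        "only_two_fields\toops",
        "Gene::1234\tGNBR::X::Gene:Gene\tGene::5678",
        "Anatomy::UBERON:0000955\tHetionet::AdG::Anatomy:Gene\tGene::1234",
    ]
    path = tmp_path / "triples.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path
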