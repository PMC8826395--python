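import numpy as np
import pytest

from hgtscan import ScoringScheme, SpeciesTreeSpec
from hgtscan.scoring import AMINO_ACIDS


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def matrix_score(scheme):
    """Substitution-score lookup shared with the oracles (data, not code)."""
    m = scheme.matrix

    def score(x: str, y: str) -> float:
        return float(m[x, y])

    return score


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture(scope="session")
def agd_species_tree() -> SpeciesTreeSpec:
    """Three-taxon dated tree shaped like the AGD comparison: a reference and
    a bridge lineage splitting 600 Ma, and a distal lineage at 2500 Ma."""
    return SpeciesTreeSpec(
        "((ref:600,bridge:600)anc:1900,distal:2500)root;", rate=3e-4
    )
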