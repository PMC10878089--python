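import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from mitoarch.io import GeneFeature, GeneOrder, Mitogenome


@pytest.fixture
def rng():
    return np.random.default_rng(20240123)


@pytest.fixture
def toy_genome():
    """10 kb genome with a few PCG/tRNA/rRNA features on both strands."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=10_000, p=[0.4, 0.1, 0.1, 0.4]))
    feats = [
        GeneFeature("cox1", "PCG", 100, 1600, "+"),
        GeneFeature("trnW", "tRNA", 1700, 1775, "+"),
        GeneFeature("rnl", "rRNA", 2000, 4000, "-"),
        GeneFeature("nad1_a", "PCG", 4200, 5100, "-"),
        GeneFeature("nad1_b", "PCG", 5300, 6200, "+"),
        GeneFeature("trnY", "tRNA", 6400, 6475, "+"),
        GeneFeature("cob", "PCG", 7000, 8200, "+"),
    ]
    return Mitogenome(id="toy", sequence=seq, features=feats)


def make_order(spec: str, genome_id: str = "g") -> GeneOrder:
    """'+a +b -c' -> GeneOrder."""
    elements = [(tok[1:], tok[0]) for tok in spec.split()]
    return GeneOrder(genome_id=genome_id, elements=elements)
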