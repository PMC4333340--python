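import numpy as np
import pytest

from finecross.fixtures import rno14_map
from finecross.genome_model import GeneticMap, Marker


@pytest.fixture
def gmap() -> GeneticMap:
    return rno14_map()


@pytest.fixture
def multi_chrom_map() -> GeneticMap:
    """Donor chromosome plus three background chromosomes."""
    markers = [
        Marker(f"D14M{i}", "14", p) for i, p in enumerate([10.0, 20.0, 30.0, 40.0, 50.0])
    ]
    for c in ("1", "2", "3"):
        markers += [
            Marker(f"D{c}M{i}", c, p) for i, p in enumerate([10.0, 40.0, 70.0, 100.0])
        ]
    return GeneticMap(markers=markers)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
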