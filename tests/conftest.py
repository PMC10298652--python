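import numpy as np
import pytest

from il_toolkit.model import GenomeMap, Marker, MarkerPanel


@pytest.fixture
def toy_genome() -> GenomeMap:
    """Three chromosomes, 60 Mbp total, lengths multiples of 1 kb."""
    return GenomeMap.from_lists(
        [
            ("chr01", 10_000_000, 60.0),
            ("chr02", 20_000_000, 80.0),
            ("chr03", 30_000_000, 100.0),
        ]
    )


@pytest.fixture
def single_chrom_genome() -> GenomeMap:
    return GenomeMap.from_lists([("chr01", 10_000_000, 100.0)])


def make_panel(genome: GenomeMap, spacing: int) -> MarkerPanel:
    markers = []
    for chrom in genome.chromosomes:
        k = 0
        for pos in range(spacing, chrom.length_bp + 1, spacing):
            k += 1
            markers.append(Marker(f"{chrom.name}_m{k:05d}", chrom.name, pos))
    return MarkerPanel(tuple(markers))


@pytest.fixture
def toy_panel(toy_genome) -> MarkerPanel:
    return make_panel(toy_genome, 1_000_000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230614)
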