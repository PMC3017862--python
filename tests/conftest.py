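import numpy as np
import pytest

from corrmut.seqdata import AlignmentRow, FamilyAlignment
from corrmut.synthetic_data import PlantedPair, SimulationConfig, simulate_family


def make_family(seqs, family_id="FAM", species=None):
    """FamilyAlignment from raw aligned strings; first row is the reference."""
    rows = []
    for i, s in enumerate(seqs):
        source = "reference" if i == 0 else "blast"
        sp = species[i] if species else ("A.thaliana" if i == 0 else f"sp{i:03d}")
        rows.append(AlignmentRow(f"s{i}", sp, source, s))
    return FamilyAlignment(family_id, rows, reference_row=0)


@pytest.fixture
def planted_family():
    """60-row, 100-column family with two strongly compensating pairs."""
    cfg = SimulationConfig(
        seed=11, n_species=60, length=100,
        planted_pairs=[PlantedPair(5, 40, "intra", 0.9),
                       PlantedPair(10, 70, "intra", 0.9)],
    )
    return cfg, simulate_family(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
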