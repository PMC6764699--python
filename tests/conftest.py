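import numpy as np
import pytest

from ascscan.null_models import DinucleotideModel
from ascscan.sequence_io import STOP_SETS, GenomeUTRSet, UTRRecord

TT11 = STOP_SETS[11]
TT4 = STOP_SETS[4]


@pytest.fixture
def uniform_model():
    return DinucleotideModel(np.full(4, 0.25), np.full((4, 4), 0.25))


def random_model(rng: np.random.Generator) -> DinucleotideModel:
    """Random chain: Dirichlet initial and rows."""
    initial = rng.dirichlet(np.ones(4))
    transition = np.vstack([rng.dirichlet(np.ones(4)) for _ in range(4)])
    return DinucleotideModel(initial, transition)


def toy_utr_set(windows, stops=None, stop_set=TT11, genome_id="toy", classes=None):
    stops = stops or ["TAA"] * len(windows)
    classes = classes or ["NA"] * len(windows)
    records = [
        UTRRecord(f"g{i}", s, w, c) for i, (s, w, c) in enumerate(zip(stops, windows, classes))
    ]
    return GenomeUTRSet(genome_id, stop_set, 0.5, records)
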