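import numpy as np
import pytest

from barcodegap.distances import DistanceMatrix
from barcodegap.sequence_io import AlignedMarkerSet, SampleRecord


def make_marker_set(name, entries):
    """entries: list of (sample_id, species, sequence)."""
    return AlignedMarkerSet(name, tuple(SampleRecord(s, sp, seq) for s, sp, seq in entries))


def make_dm(ids, species, values, marker="test"):
    """Build a DistanceMatrix directly from a (possibly NaN-holed) array."""
    return DistanceMatrix(tuple(ids), dict(species), np.asarray(values, float), None, marker)


@pytest.fixture
def two_species_alignment():
    """Two species x two individuals; clean separation, one intra difference."""
    return make_marker_set(
        "toy",
        [
            ("a1", "Oberonia_alpha", "AAAAAAAAAACCCCCCCCCC"),
            ("a2", "Oberonia_alpha", "AAAAAAAAAACCCCCCCCCT"),
            ("b1", "Oberonia_beta", "GGGGGGGGGGCCCCCCCCCC"),
            ("b2", "Oberonia_beta", "GGGGGGGGGGCCCCCCCCCT"),
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
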