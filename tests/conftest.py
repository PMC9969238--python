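import numpy as np
import pytest

from barcodekit import (
    ReferenceLibrary,
    SequenceRecord,
    SimulationConfig,
    simulate_library,
)
from barcodekit.simulate import random_coding_sequence


def make_record(rid, seq, **kw):
    return SequenceRecord(record_id=rid, sequence=seq, **kw)


@pytest.fixture(scope="session")
def separated_library():
    """Well-separated simulated library: intra << inter, no corruption."""
    cfg = SimulationConfig(
        n_species=12,
        records_per_species={"mean": 3.0, "singleton_fraction": 0.25},
        intra_branch=0.005,
        inter_branch=0.04,
        seed=11,
    )
    lib, truth = simulate_library(cfg)
    return lib, truth


@pytest.fixture(scope="session")
def small_matrix_library():
    """Tiny deterministic library for distance-matrix unit tests."""
    rng = np.random.default_rng(5)
    base = random_coding_sequence(300, rng=rng)
    recs = []
    for i in range(6):
        seq = list(base)
        # mutate i distinct sites deterministically
        for k in range(i):
            pos = 10 * k + 3
            seq[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[seq[pos]]
        recs.append(make_record(f"r{i}", "".join(seq)))
    return ReferenceLibrary(records=recs)


def grading_fixture_library():
    """Six species engineered to earn grades A, B, C, D, E, E.

    12 records / 1 exclusive BIN -> A; 5 / 1 BIN -> B; 4 records across 2
    exclusive BINs -> C; 2 records / 1 BIN -> D; and a pair of species
    sharing one BIN -> E, E.
    """
    rng = np.random.default_rng(42)
    seq = random_coding_sequence(510, rng=rng)
    plan = [
        ("Alpha prima", [("BOLD:AAA0001", 12)]),
        ("Beta secunda", [("BOLD:BBB0001", 5)]),
        ("Gamma tertia", [("BOLD:CCC0001", 2), ("BOLD:CCC0002", 2)]),
        ("Delta quarta", [("BOLD:DDD0001", 2)]),
        ("Epsilon quinta", [("BOLD:EEE0001", 3)]),
        ("Zeta sexta", [("BOLD:EEE0001", 4)]),
    ]
    recs = []
    i = 0
    for species, bins in plan:
        for bin_id, n in bins:
            for _ in range(n):
                i += 1
                recs.append(
                    make_record(
                        f"g{i:03d}", seq, species_name=species,
                        genus=species.split()[0], subfamily="Chironominae",
                        family="Chironomidae", bin_id=bin_id,
                    )
                )
    return ReferenceLibrary(records=recs)


@pytest.fixture
def grading_library():
    return grading_fixture_library()
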