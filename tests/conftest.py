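import numpy as np
import pytest

from haplopop.alignment import Alignment, PopulationMap

BASES = np.array(list("ACGT"))


def random_alignment(n, L, rng, p_variable=0.3):
    """Random alignment where a fraction of columns carry 2-4 states."""
    arr = np.tile(rng.choice(BASES, size=L), (n, 1))
    for j in rng.choice(L, max(1, int(p_variable * L)), replace=False):
        k = int(rng.integers(2, 5))
        states = rng.choice(BASES, size=k, replace=False)
        arr[:, j] = states[rng.integers(0, k, size=n)]
    return Alignment.from_array([f"s{i}" for i in range(n)], arr)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def toy_pair():
    """Two sequences of length 10 differing at 2 sites."""
    return Alignment(("a", "b"), ("ACGTACGTAC", "ACGTACGTGT"))


@pytest.fixture
def toy_triplet():
    """Three sequences with pairwise differences {2, 2, 4}."""
    return Alignment(
        ("a", "b", "c"),
        ("AAAAAAAAAA", "TTAAAAAAAA", "AATTAAAAAA"),
    )


@pytest.fixture
def two_group_alignment():
    """Two internally identical, mutually distant groups of 4 + 4."""
    s1 = "A" * 30
    s2 = "T" * 15 + "A" * 15
    ids = tuple(f"x{i}" for i in range(4)) + tuple(f"y{i}" for i in range(4))
    seqs = (s1,) * 4 + (s2,) * 4
    return Alignment(ids, seqs)


@pytest.fixture
def two_group_popmap(two_group_alignment):
    return PopulationMap(
        {sid: ("X" if sid.startswith("x") else "Y") for sid in two_group_alignment.ids}
    )


@pytest.fixture(scope="session")
def preset_dataset():
    """One realization of the five-deme two-region preset (session cached)."""
    from haplopop import synthdata as sd

    return sd.simulate_dataset(sd.two_region_preset(seed=5))


def write_inputs(tmp_path, aln, pm):
    fasta = tmp_path / "aln.fasta"
    popmap = tmp_path / "popmap.tsv"
    with open(fasta, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n{seq}\n")
    with open(popmap, "w") as fh:
        for sid, pop in pm.assignment.items():
            fh.write(f"{sid}\t{pop}\n")
    return fasta, popmap
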