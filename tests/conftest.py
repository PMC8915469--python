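import numpy as np
import pytest

from damlitter import (
    DistanceMatrix,
    PresenceMatrix,
    SyntheticConfig,
    encode_presence,
    generate,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def toy_csv(tmp_path):
    """Three data rows: one puppy rectal sample with two isolations plus a
    sterile dam sample (metadata-only row)."""
    text = (
        "sample_id,family_id,subject_id,subject_role,matrix,time_point,genus,species,growth\n"
        "s1,A01,A01-p1,puppy,rectal,T2,Escherichia,Escherichia coli,high\n"
        "s1,A01,A01-p1,puppy,rectal,T2,Proteus,Proteus mirabilis,low\n"
        "s2,A01,A01-dam,dam,rectal,T2,,,\n"
    )
    path = tmp_path / "toy.csv"
    path.write_text(text)
    return path


@pytest.fixture
def convergent_dataset():
    """One default convergent synthetic dataset with its presence matrix."""
    samples, records, truth = generate(SyntheticConfig(seed=7))
    matrix = encode_presence(records, samples)
    return samples, records, truth, matrix


def random_distance_matrix(rng, n, labels=None):
    """Random symmetric distance matrix with distinct off-diagonal entries."""
    m = rng.random((n, n))
    d = (m + m.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels or [f"s{i}" for i in range(n)], d)


def random_presence(rng, n, g):
    vals = rng.integers(0, 2, size=(n, g))
    return PresenceMatrix([f"s{i}" for i in range(n)],
                          [f"G{j}" for j in range(g)], vals)
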