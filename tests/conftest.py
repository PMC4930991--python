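import numpy as np
import pytest

from coalabc.synthetic_data import make_edge_case_fixtures


@pytest.fixture(scope="session")
def edge_fixtures():
    return make_edge_case_fixtures(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_alignment_dataset(rng, n_seq=8, length=40, n_loci=1, p_mut=0.06):
    """Random two-species dataset for brute-force oracle comparisons."""
    from coalabc.seq_data import (
        LocusAlignment,
        LocusSpec,
        MultiLocusDataset,
        SampleRecord,
    )

    assert n_seq % 4 == 0
    half = n_seq // 2
    samples = [
        SampleRecord(f"a{i}", "P1", "asp") for i in range(half // 2)
    ] + [SampleRecord(f"c{i}", "P2", "cra") for i in range(half // 2)]
    ids = [(s.sample_id, k) for s in samples for k in (1, 2)]
    alns = []
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for l in range(n_loci):
        mat = np.tile(bases[rng.integers(0, 4, size=length)], (n_seq, 1))
        mut = rng.random((n_seq, length)) < p_mut
        mat[mut] = bases[rng.integers(0, 4, size=int(mut.sum()))]
        alns.append(
            LocusAlignment(LocusSpec(f"L{l}", length), mat, list(ids))
        )
    return MultiLocusDataset(samples, alns)
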