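import numpy as np
import pytest

import chipcalib as cc


@pytest.fixture(scope="session")
def small_pair() -> cc.GenomePair:
    """Two chromosomes per species, 5 kb each, 50 bp reads."""
    return cc.gen_genome_pair(seed=1, n_chrom=2, chrom_len=5000, read_length=50)


@pytest.fixture
def toy_depth() -> cc.DepthTrack:
    rng = np.random.default_rng(42)
    lengths = {"exp_1": 200, "exp_2": 150}
    values = {c: rng.integers(0, 10, size=n).astype(np.int64) for c, n in lengths.items()}
    return cc.DepthTrack(values=values, chrom_lengths=lengths)


@pytest.fixture
def fig6a_table() -> cc.CytologyTable:
    """Scored-cell counts: 100 metaphase cells per strain."""
    return cc.CytologyTable(
        [
            cc.CytologyRow("ctf4_empty_vector", 100, 49),
            cc.CytologyRow("ctf8_empty_vector", 100, 47),
            cc.CytologyRow("ctf8_2mu_CHL1", 100, 18),
            cc.CytologyRow("ctf4_2mu_CHL1", 100, 40),
        ]
    )
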