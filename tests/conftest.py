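import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from chromintegrate.genomic_model import GenomicInterval
from chromintegrate.synthetic_data import SimulationConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_intervals(rng, n, seqs=("chr1", "chr2"), span=2000, max_len=60):
    out = []
    for _ in range(n):
        seq = seqs[rng.integers(len(seqs))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(seq, start, start + length))
    return out


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """Noiseless 40-gene simulation shared by read-only tests."""
    cfg = SimulationConfig(
        seed=7,
        n_genes=40,
        n_up=12,
        n_down=4,
        replicate_sd=0.0,
        n_background_peaks=30,
        n_intragenic_unique=6,
    )
    outdir = tmp_path_factory.mktemp("smallsim")
    return simulate(cfg, outdir)
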