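import numpy as np
import pytest

from zwscreen.simulate import (
    CountMatrix,
    PoolDesign,
    simulate_count_matrix,
    simulate_transcriptome,
)

BASES = np.array(list("ACGT"))


def random_seq(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(BASES, length))


@pytest.fixture(scope="session")
def demo_simulation():
    """1,000-transcript demo universe with the standard 6+6 pooled design."""
    design = PoolDesign(seed=3)
    transcripts = simulate_transcriptome(1000, seed=3, design=design)
    matrix = simulate_count_matrix(transcripts, design)
    return transcripts, matrix


@pytest.fixture()
def tiny_matrix():
    """Hand-built 4-contig matrix covering the screen's criterion edges."""
    counts = np.array(
        [
            [50, 60, 55, 45, 50, 52, 0, 0, 0, 0, 0, 0],   # female-exclusive, long
            [50, 60, 55, 45, 50, 52, 1, 0, 0, 0, 0, 0],   # one male read
            [30, 35, 33, 28, 31, 30, 0, 0, 0, 0, 0, 0],   # exclusive but 500 bp
            [20, 22, 21, 19, 20, 21, 20, 22, 21, 19, 20, 21],  # unbiased
        ],
        dtype=np.int64,
    )
    return CountMatrix(
        contig_ids=["cand_ok", "cand_maleread", "cand_short", "flat"],
        pool_ids=[f"F{i}" for i in range(1, 7)] + [f"M{i}" for i in range(1, 7)],
        pool_sex=["F"] * 6 + ["M"] * 6,
        library_size=np.full(12, 1e6),
        contig_length=np.array([800, 800, 500, 800]),
        counts=counts,
    )
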