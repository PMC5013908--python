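import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20231101)


@pytest.fixture
def tiny_sumstats(tmp_path):
    """Three-variant beta/SE table on disk, z = 2 for every row."""
    path = tmp_path / "sumstats.tsv"
    path.write_text(
        "SNP\tCHR\tBP\tBETA\tSE\n"
        "rs1\t1\t1000\t0.2\t0.1\n"
        "rs2\t1\t2000\t0.2\t0.1\n"
        "rs3\t2\t500\t0.2\t0.1\n"
    )
    return path
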