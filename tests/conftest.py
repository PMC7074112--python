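import numpy as np
import pandas as pd
import pytest

from isoswitch import SimulationConfig, simulate_cell_panel, simulate_cohort


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def cohort(default_cfg):
    """Default synthetic cohort (isoform matrix, metadata, truth)."""
    return simulate_cohort(default_cfg)


@pytest.fixture(scope="session")
def panel(default_cfg):
    """Default synthetic cell-line panel (matrix, true classes, planted genes)."""
    return simulate_cell_panel(default_cfg)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A fast, small cohort configuration for loops over replicates."""
    return SimulationConfig(
        n_tumor=100, n_normal=40, n_genes=160,
        signature_block_size=40, ratio_block_size=30, seed=0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_iso():
    """Two NF-YA transcripts plus two one-transcript genes, 4 samples."""
    from isoswitch import IsoformMatrix

    tpm = pd.DataFrame(
        {
            "s1": [10.0, 10.0, 4.0, 6.0],
            "s2": [30.0, 10.0, 1.0, 0.0],
            "s3": [5.0, 0.0, 2.0, 2.0],
            "s4": [70.0, 10.0, 3.0, 3.0],
        },
        index=["NFYA-s", "NFYA-l", "GA.1", "GA.2"],
    )
    genes = pd.Series(["NFYA", "NFYA", "GA", "GA"], index=tpm.index)
    return IsoformMatrix(tpm, genes)
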