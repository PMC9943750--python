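import numpy as np
import pandas as pd
import pytest

from prometa import BlockSpec, CausalEffect, SimulationScenario, simulate_ld_panel


@pytest.fixture(scope="session")
def small_panel():
    """300-sample, 40-variant single-block panel with moderate LD."""
    return simulate_ld_panel(300, [BlockSpec(40, (0.1, 0.5), 0.9)], seed=11)


@pytest.fixture(scope="session")
def two_block_panel():
    """Two independent LD blocks on different chromosomes."""
    return simulate_ld_panel(
        500,
        [BlockSpec(30, (0.1, 0.5), 0.9, "1"), BlockSpec(30, (0.1, 0.5), 0.9, "2")],
        seed=12,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_sumstats(markers, beta, se, eaf=0.3, n=10_000, chrom="1", pos0=1_000_000):
    """Hand-rolled summary table with passing QC columns."""
    m = len(markers)
    beta = np.broadcast_to(np.asarray(beta, float), (m,))
    se = np.broadcast_to(np.asarray(se, float), (m,))
    eaf = np.broadcast_to(np.asarray(eaf, float), (m,))
    from scipy import stats

    z = np.divide(beta, se, out=np.zeros(m), where=se > 0)
    return pd.DataFrame(
        {
            "MARKER": markers,
            "CHR": chrom,
            "POS": pos0 + 2000 * np.arange(m),
            "EA": "A",
            "NEA": "G",
            "EAF": eaf,
            "BETA": beta,
            "SE": se,
            "P": 2 * stats.norm.sf(np.abs(z)),
            "N": n,
            "INFO": 0.99,
            "HWE_P": 0.5,
            "CALLRATE": 0.999,
        }
    )


@pytest.fixture
def sumstats_factory():
    return make_sumstats
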