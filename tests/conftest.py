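import numpy as np
import pandas as pd
import pytest

from chipscan import simulate as sim


@pytest.fixture(scope="session")
def small_array():
    """A 300-gene synthetic array with spiked regions (shared, read-only)."""
    cfg = sim.SimulationConfig(n_genes=300, seed=7)
    probes, genes, truth = sim.simulate_array(cfg)
    return cfg, probes, genes, truth


@pytest.fixture(scope="session")
def null_array():
    """A pure-null synthetic array (effect_size = 0)."""
    cfg = sim.SimulationConfig(n_genes=300, effect_size=0.0, seed=11)
    probes, genes, truth = sim.simulate_array(cfg)
    return cfg, probes, genes, truth


def make_stats(starts, pvalues, chrom="chr1", probe_len=60, chroms=None):
    """Hand-built ProbeStat frame for caller tests."""
    starts = list(starts)
    chrom_col = list(chroms) if chroms is not None else [chrom] * len(starts)
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(len(starts))],
            "chrom": chrom_col,
            "start": starts,
            "end": [s + probe_len for s in starts],
            "combined_z": np.zeros(len(starts)),
            "p_value": list(pvalues),
        }
    )
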