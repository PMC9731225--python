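import numpy as np
import pandas as pd
import pytest

from imputebench import HaplotypePanel, PopSpec, SimConfig, simulate_populations


def make_panel(haps, pos=None, contig="1", phased=True, ref=None, alt=None):
    """Small hand-rolled HaplotypePanel from a (2n, S) allele matrix."""
    haps = np.asarray(haps, dtype=np.int8)
    n_sites = haps.shape[1]
    if pos is None:
        pos = np.arange(n_sites) * 1000 + 100
    sites = pd.DataFrame(
        {
            "contig": contig,
            "pos": np.asarray(pos),
            "ref": ref if ref is not None else ["A"] * n_sites,
            "alt": alt if alt is not None else ["G"] * n_sites,
        }
    )
    samples = [f"S{i}" for i in range(haps.shape[0] // 2)]
    return HaplotypePanel(sites=sites, haplotypes=haps, sample_ids=samples, phased=phased)


@pytest.fixture(scope="session")
def small_sim_pair():
    """Two modestly diverged populations for generic integration tests."""
    cfg = SimConfig(
        n_sites=400,
        seq_length_cM=2.0,
        pops=(PopSpec("A", 200, 80), PopSpec("B", 200, 80)),
        split_generations=150,
        mixing_generations=80,
        seed=42,
    )
    return simulate_populations(cfg)
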