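import numpy as np
import pandas as pd
import pytest

from panelancestry import (HMMParams, ReferencePanel, simulate_admixed_cohort,
                           simulate_reads, simulate_reference_panel)


@pytest.fixture(scope="session")
def small_panel():
    """3 populations + AJ subpanel, 300 sites: shared by cheap tests."""
    return simulate_reference_panel(m_sites=300, n_hap_per_pop=30,
                                    n_hap_subpop=20, seed=101)


@pytest.fixture(scope="session")
def small_truth(small_panel):
    return simulate_admixed_cohort(small_panel, 40, dirichlet_alpha=0.1,
                                   subpop_fraction=0.15, seed=102)


@pytest.fixture(scope="session")
def small_pileup(small_truth):
    return simulate_reads(small_truth, mean_depth=1.0, error_rate=0.01, seed=103)


def tiny_panel(n_hap, m, seed=0, pops=("A", "B")):
    """Small hand-seeded panel for oracle tests (no subpanel)."""
    rng = np.random.default_rng(seed)
    hap = rng.integers(0, 2, size=(n_hap, m)).astype(np.uint8)
    # ensure no monomorphic column (keeps priors informative but proper)
    for j in range(m):
        if hap[:, j].all() or not hap[:, j].any():
            hap[rng.integers(0, n_hap), j] ^= 1
    sites = pd.DataFrame({"chrom": "1", "pos": np.arange(1, m + 1) * 10,
                          "ref": "A", "alt": "C"})
    labels = np.array([pops[i % len(pops)] for i in range(n_hap)])
    return ReferencePanel(sites=sites, haplotypes=hap, pop_label=labels)
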