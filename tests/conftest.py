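import numpy as np
import pandas as pd
import pytest

from spermage.core import MethylomeDataset, ProbeManifest
from spermage.outcomes import couples_to_frame
from spermage.simulate import SimulationConfig, simulate_cohort


def make_dataset(beta: np.ndarray, chrom="chr1", positions=None, subject_ids=None):
    """Small MethylomeDataset from a raw beta matrix."""
    p, n = beta.shape
    positions = positions if positions is not None else 1000 * (np.arange(p) + 1)
    man = ProbeManifest(pd.DataFrame({
        "probe_id": [f"cg{i:05d}" for i in range(p)],
        "chrom": [chrom] * p,
        "pos": positions,
    }))
    ids = subject_ids or [f"s{j}" for j in range(n)]
    return MethylomeDataset(man, beta, ids)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated cohort reused across read-only tests."""
    cfg = SimulationConfig(
        n_couples=80, n_probes=1200, n_chromosomes=3,
        n_age_cpgs=40, n_age_regions=15, seed=11,
    )
    ds, couples, truth = simulate_cohort(cfg)
    return cfg, ds, couples, truth


@pytest.fixture(scope="session")
def small_pheno(small_cohort):
    _, _, couples, _ = small_cohort
    return couples_to_frame(couples)
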