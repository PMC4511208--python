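import numpy as np
import pandas as pd
import pytest

from seldrift.cohort import CohortPanel, SnpRecord
from seldrift.simulate import SimConfig, simulate_three_cohorts


def make_panel(dosages, cohort_id="X", snp_ids=None, candidates=(), alleles=None):
    """Build a small panel from a dense dosage matrix (rows = individuals)."""
    dosages = np.asarray(dosages, dtype=float)
    n_snps = dosages.shape[1]
    snp_ids = snp_ids or [f"rs{i + 1}" for i in range(n_snps)]
    alleles = alleles or [("A", "G")] * n_snps
    snps = [
        SnpRecord(sid, "1", (i + 1) * 100, a, b, sid in candidates)
        for i, (sid, (a, b)) in enumerate(zip(snp_ids, alleles))
    ]
    return CohortPanel(cohort_id=cohort_id, snps=snps, dosages=dosages)


@pytest.fixture
def tiny_panel():
    return make_panel([[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 2]])


@pytest.fixture(scope="session")
def sim_panels():
    """Three moderately sized cohorts with drift and missingness."""
    config = SimConfig(
        n_snps=40,
        n_individuals=(120, 100, 80),
        drift=(0.05, 0.02, 0.08),
        missing_rate=(0.05, 0.05, 0.05),
        candidate_indices=(3, 17, 31),
        seed=11,
    )
    return simulate_three_cohorts(config)


def maf_frame(m, s2=None, n_geno=None):
    """Construct a MafTable-compatible frame from a dict snp_id -> m."""
    ids = list(m)
    mv = np.array([m[s] for s in ids], dtype=float)
    n = np.array([n_geno[s] if n_geno else 100 for s in ids])
    frame = pd.DataFrame(
        {
            "m": mv,
            "s2": np.array([s2[s] if s2 else 0.5 for s in ids], dtype=float),
            "n_geno": n,
            "x_count": np.round(mv * 2 * n).astype(int),
            "n_hap": 2 * n,
            "call_rate": 1.0,
        },
        index=pd.Index(ids, name="snp_id"),
    )
    return frame
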