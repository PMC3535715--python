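import numpy as np
import pandas as pd
import pytest

import crossrank as cr
from crossrank.simulate import SimulationConfig, simulate_study


@pytest.fixture
def toy_genes() -> pd.DataFrame:
    """Five handmade genes on two chromosomes (1-based inclusive)."""
    return pd.DataFrame(
        {
            "gene_id": ["G1", "G2", "G3", "G4", "G5"],
            "symbol": ["AAA", "BBB", "CCC", "DDD", "EEE"],
            "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2"],
            "start": [100_000, 115_000, 400_000, 50_000, 300_000],
            "end": [120_000, 140_000, 450_000, 80_000, 340_000],
        }
    )


@pytest.fixture(scope="session")
def small_study():
    """One compact simulated study shared by read-only tests."""
    cfg = SimulationConfig(seed=7, n_genes=800, n_snps=8000)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_analysis(small_study):
    """Profiles, QC-passing SNPs, and the SNP-gene mapping for small_study."""
    study = small_study
    sets = dict(study.evidence.source_sets)
    sets["HuLink"] = cr.assign_linkage(study.genes, study.evidence.linkage_intervals)
    profiles, _ = cr.build_profiles(study.genes, sets)
    snps, _ = cr.qc_filter(study.snps)
    mapping, gene_index, _ = cr.map_snps_to_genes(snps, study.genes)
    return {
        "study": study,
        "profiles": profiles,
        "snps": snps,
        "mapping": mapping,
        "gene_index": gene_index,
    }


def brute_force_q(p, pi0: float) -> np.ndarray:
    """Independent double-loop q-value oracle straight from the definition:
    q_i = min over j with p_j >= p_i of pi0 * m * p_j / rank_j, where
    rank_j counts p-values <= p_j (max-rank for ties)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    q = np.empty(m)
    for i in range(m):
        candidates = []
        for j in range(m):
            if p[j] >= p[i]:
                rank_j = int(np.sum(p <= p[j]))
                candidates.append(pi0 * m * p[j] / rank_j)
        q[i] = min(1.0, min(candidates))
    return q
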