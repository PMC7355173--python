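import numpy as np
import pandas as pd
import pytest

from gxescan import (
    CohortData,
    GeneSpec,
    ScanModelSpec,
    SimConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def null_cohort() -> CohortData:
    """Desk-scale null cohort (no G-by-E effect) shared across tests."""
    config = SimConfig(
        n_individuals=400,
        genes=[
            GeneSpec(f"G{i:03d}", n_snps=2 + i % 4, ld_rho=(0.2, 0.5, 0.8)[i % 3])
            for i in range(12)
        ],
        seed=42,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def hp_spec() -> ScanModelSpec:
    return ScanModelSpec(exposure="harsh_punitive_control")


@pytest.fixture()
def tiny_cohort() -> CohortData:
    """Hand-checkable 6-sample, 3-SNP cohort with complete data."""
    genotypes = np.array(
        [
            [0, 1, 2],
            [1, 0, 1],
            [2, 1, 0],
            [0, 2, 1],
            [1, 1, 1],
            [2, 0, 0],
        ],
        dtype=float,
    )
    gene_map = pd.DataFrame(
        {
            "snp_id": ["s1", "s2", "s3"],
            "gene_id": ["gA", "gA", "gB"],
            "chrom": [1, 1, 2],
            "pos": [100, 200, 300],
        }
    )
    pheno = pd.DataFrame(
        {
            "symptom_score": [1.0, 2.0, 1.5, 2.5, 1.0, 3.0],
            "hp": [1.0, 1.0, 2.0, 4.0, 1.0, 3.0],
            "age": [13.0, 14.0, 13.5, 12.9, 14.2, 13.8],
            "sex": [0.0, 1.0, 0.0, 1.0, 1.0, 0.0],
        },
        index=pd.Index([f"S{i}" for i in range(6)], name="sample_id"),
    )
    return CohortData(
        genotypes=genotypes,
        snp_ids=["s1", "s2", "s3"],
        sample_ids=[f"S{i}" for i in range(6)],
        gene_map=gene_map,
        pheno=pheno,
    )
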