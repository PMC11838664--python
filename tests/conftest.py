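"""Shared fixtures: small simulated panels and summary statistics.

Everything is generated programmatically with fixed seeds; no binary
fixtures are stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from gtaccc.ldsc import LDScoreTable, multivariate_ldsc
from gtaccc.simulate import (
    TruthRecord,
    simulate_genotypes,
    simulate_item_phenotypes,
    simulate_sumstats_direct,
    synthetic_ld_scores,
    thresholds_from_prevalence,
)


@pytest.fixture(scope="session")
def small_panel():
    """2,000 individuals x 300 variants, 15 LD blocks, moderate LD."""
    return simulate_genotypes(
        n_ind=2000, n_var=300, n_blocks=15, r=0.5, maf_range=(0.1, 0.5), seed=11
    )


@pytest.fixture(scope="session")
def big_null_panel():
    """Independent variants for null-calibration checks."""
    return simulate_genotypes(
        n_ind=1500, n_var=2000, n_blocks=2000, r=0.0, maf_range=(0.1, 0.5), seed=12
    )


@pytest.fixture(scope="session")
def item_cohort(small_panel):
    truth = TruthRecord(
        h2_low=0.6,
        h2_high=0.6,
        rg_fact=0.6,
        weights=list(np.arange(12) / 11),
        thresholds=list(thresholds_from_prevalence(np.linspace(0.75, 0.25, 12))),
        seed=21,
    )
    return simulate_item_phenotypes(small_panel, truth, 12)


@pytest.fixture(scope="session")
def direct_pair():
    """Two direct-simulated traits with rg = 0.5 plus their LD score table."""
    M = 2000
    ld_vals = synthetic_ld_scores(M, mean=3.0, spread=2.0, seed=31)
    traits = simulate_sumstats_direct(
        ld_vals,
        M,
        [{"h2": 0.5, "N": 50_000, "trait_id": "t1"}, {"h2": 0.5, "N": 50_000, "trait_id": "t2"}],
        rg_matrix=np.array([[1.0, 0.5], [0.5, 1.0]]),
        seed=32,
    )
    ld = LDScoreTable(snp=traits[0].df["SNP"].to_numpy(), ld=ld_vals, M=M)
    return traits, ld


@pytest.fixture(scope="session")
def trio_struct():
    """GeneticCovStruct from three direct-simulated traits with known rg."""
    M = 2000
    rgm = np.array([[1.0, 0.8, 0.2], [0.8, 1.0, 0.5], [0.2, 0.5, 1.0]])
    ld_vals = synthetic_ld_scores(M, mean=3.0, spread=2.0, seed=41)
    traits = simulate_sumstats_direct(
        ld_vals,
        M,
        [{"h2": 0.4, "N": 50_000, "trait_id": f"t{i + 1}"} for i in range(3)],
        rg_matrix=rgm,
        seed=42,
    )
    ld = LDScoreTable(snp=traits[0].df["SNP"].to_numpy(), ld=ld_vals, M=M)
    struct = multivariate_ldsc(traits, ld, n_blocks=200)
    return struct, rgm
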