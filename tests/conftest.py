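import logging

import numpy as np
import pandas as pd
import pytest

import rulebench as rb

logging.getLogger("rulebench").setLevel(logging.ERROR)

GENOTYPES = ("AA", "AB", "BB")


def genotype_frame(rng: np.random.Generator, n: int, snps: int) -> pd.DataFrame:
    g = rng.choice(GENOTYPES, size=(n, snps))
    return pd.DataFrame(
        {
            f"rs{i + 1}": pd.Categorical(g[:, i], categories=list(GENOTYPES))
            for i in range(snps)
        }
    )


@pytest.fixture(scope="session")
def model_a_dataset() -> rb.Dataset:
    """Noise-free two-SNP interaction cohort: 10 SNPs, 600 subjects."""
    return rb.generate_dataset(rb.SimulationConfig("A", 10, 600, 0.0, 0.0, seed=42))


@pytest.fixture(scope="session")
def model_b_dataset() -> rb.Dataset:
    """Noise-free gene-environment cohort: 15 SNPs + AUC, 600 subjects."""
    return rb.generate_dataset(rb.SimulationConfig("B", 15, 600, 0.0, 0.0, seed=42))


@pytest.fixture(scope="session")
def single_snp_fixture():
    """rs1 = AA if and only if Case; three irrelevant SNPs, 300 subjects."""
    rng = np.random.default_rng(5)
    frame = genotype_frame(rng, 300, 4)
    labels = np.where(frame["rs1"] == "AA", "Case", "Control").astype(object)
    return frame, labels
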