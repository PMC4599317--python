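import numpy as np
import pandas as pd
import pytest

from meqtlscan.simulate import (
    ProbeSpec,
    SimulationConfig,
    SnpSpec,
    blood_config,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """350-sample cohort, 3 SNPs x 15 probes, two planted effects."""
    cfg = blood_config(
        n_samples=350, n_snps=3, probes_per_snp=15,
        effects={(0, 0): 0.8, (1, 1): -0.8}, noise_sd=0.5,
        maf_range=(0.3, 0.3), seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def tiny_config():
    """Hand-written 2-SNP / 3-probe configuration for exact checks."""
    return SimulationConfig(
        n_samples=60,
        snp_specs=(
            SnpSpec("rsA", "chr1", 1_000_000, "A", 0.4),
            SnpSpec("rsB", "chr1", 3_000_000, "C", 0.2),
        ),
        probe_specs=(
            ProbeSpec("cg01", "chr1", 1_000_500, 0.5),
            ProbeSpec("cg02", "chr1", 1_400_000, -1.0),
            ProbeSpec("cg03", "chr1", 3_000_000, 1.5),
        ),
        effect_specs={("rsA", "cg01"): 1.0},
        noise_sd=0.3,
        seed=5,
    )


@pytest.fixture
def toy_genes():
    """Two genes on chr1: + strand TSS at 10001, - strand TSS at 60000."""
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [10_000, 40_000],
            "end": [30_000, 60_000],
            "name": ["GA", "GB"],
            "score": [0, 0],
            "strand": ["+", "-"],
        }
    )


def ols_loglik_lrt(X_full, X_red, y):
    """Independent Gaussian-likelihood LRT oracle via normal equations."""
    n = len(y)

    def loglik(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        rss = float(resid @ resid)
        return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1), rss

    ll_full, rss_full = loglik(X_full)
    ll_red, rss_red = loglik(X_red)
    return 2.0 * (ll_full - ll_red), rss_red, rss_full
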