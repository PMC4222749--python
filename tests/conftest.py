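import numpy as np
import pytest

from seasonscan.synth import (TruthConfig, frost_study_plan, simulate_study,
                              simulate_truth)


@pytest.fixture(scope="session")
def null_study():
    """Pure-noise study: no planted seasonal or clinal SNPs."""
    cfg = TruthConfig(n_snps=3000, frac_seasonal=0.0, frac_clinal=0.0, seed=101)
    truth = simulate_truth(cfg)
    table, metas = simulate_study(truth, cfg)
    return truth, table, metas


@pytest.fixture(scope="session")
def seasonal_study():
    """Study with 5% planted seasonal oscillators (amplitude 0.20)."""
    cfg = TruthConfig(n_snps=4000, frac_seasonal=0.05, seed=102)
    truth = simulate_truth(cfg)
    table, metas = simulate_study(truth, cfg)
    return truth, table, metas


@pytest.fixture(scope="session")
def frost_null_study():
    """Pure-noise study including a post-frost sample (no frost effect).

    Dense genome (many SNPs per 50-kb window) so the one-per-window block
    bootstrap genuinely resamples the focal set and its CIs carry
    focal-side sampling noise.
    """
    cfg = TruthConfig(n_snps=6000, chrom_plan=(("2L", 3_000_000),),
                      frac_seasonal=0.0, frost_shift=0.0,
                      sampling_plan=frost_study_plan(), seed=103)
    truth = simulate_truth(cfg)
    table, metas = simulate_study(truth, cfg)
    return truth, table, metas


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
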