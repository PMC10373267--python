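import numpy as np
import pandas as pd
import pytest

from gcgut import SimConfig, fit_dabc, simulate_cohort, simulate_da_dataset


@pytest.fixture(scope="session")
def da_dataset():
    """A benchmark DA dataset with known coefficients (200 x 150)."""
    return simulate_da_dataset(seed=11)


@pytest.fixture(scope="session")
def da_fit(da_dataset):
    table, design, _ = da_dataset
    return fit_dabc(table, design)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort."""
    cfg = SimConfig(n_dyads=12, n_features=60, n_per_class=3,
                    n_gc_samples_per_window=3,
                    n_offspring_samples_per_season=2, seed=5)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_dabc_fit(p_bh_values, predictor="EarlyPreGC"):
    """Construct a minimal DabcFit with prescribed BH-adjusted p-values."""
    from gcgut.dabc import DabcFit

    feats = [f"g{i}" for i in range(len(p_bh_values))]
    cols = [predictor]
    zeros = pd.DataFrame(0.0, index=feats, columns=cols)
    p_bh = pd.DataFrame({predictor: p_bh_values}, index=feats)
    return DabcFit(
        beta=zeros.copy(), se=zeros.copy(), W=zeros.copy(),
        p=p_bh.copy(), p_bh=p_bh, significant=p_bh < 0.05,
        log_sampling_fraction=pd.Series(dtype=float), n_iter=0, converged=True,
    )
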