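import numpy as np
import pytest

from prstune.harmonize import harmonize
from prstune.ld import compute_ld
from prstune.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_variants=120, block_size=10, within_block_r=0.6,
        maf_range=(0.1, 0.5), fraction_causal=0.1, heritability=0.5,
        prevalence=0.36, n_train=3000, n_target=500, n_reference=300,
        seed=11,
    )


@pytest.fixture(scope="session")
def study(small_config):
    return simulate_study(small_config, seed=11)


@pytest.fixture(scope="session")
def harmonized(study):
    return harmonize(study.summary_stats, study.target)


@pytest.fixture(scope="session")
def reference_ld(study):
    return compute_ld(study.reference, window_kb=250.0)


def naive_correlation(dosages):
    """Independent double-loop Pearson correlation oracle."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            xi, xj = d[:, i], d[:, j]
            xi = np.where(np.isnan(xi), np.nanmean(xi), xi)
            xj = np.where(np.isnan(xj), np.nanmean(xj), xj)
            si, sj = xi.std(), xj.std()
            if si == 0 or sj == 0:
                out[i, j] = 1.0 if i == j else 0.0
            else:
                out[i, j] = ((xi - xi.mean()) * (xj - xj.mean())).mean() / (si * sj)
    return out
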