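import numpy as np
import pandas as pd
import pytest

from polyfactor import demo
from polyfactor.ldsc import GeneticCovarianceEstimate
from polyfactor.simdata import make_ld_panel


@pytest.fixture(scope="session")
def nine_trait_structure():
    """True 9-trait / 3-factor architecture matching the bundled study."""
    traits = demo.TRAITS
    k, q = 9, 3
    Lam = np.zeros((k, q))
    for fj, fname in enumerate(demo.FACTORS):
        for t in demo.FACTOR_PATTERN[fname]:
            Lam[traits.index(t), fj] = demo.LOADINGS[t]
    Phi = np.full((q, q), demo.FACTOR_CORR)
    np.fill_diagonal(Phi, 1.0)
    Theta = np.array([demo.RESIDUALS[t] for t in traits])
    return traits, Lam, Phi, Theta


@pytest.fixture(scope="session")
def exact_estimate(nine_trait_structure):
    """A covariance estimate built exactly from the true structure."""
    traits, Lam, Phi, Theta = nine_trait_structure
    S = Lam @ Phi @ Lam.T + np.diag(Theta)
    n_el = 9 * 10 // 2
    return GeneticCovarianceEstimate(S=S, V=np.eye(n_el) * 1e-4,
                                     intercepts=np.eye(9),
                                     trait_names=traits, n_blocks=200)


@pytest.fixture(scope="session")
def small_panel():
    """A small LD panel shared by fast unit tests."""
    return make_ld_panel(n_ref=500, n_blocks=20, block_size=20, rho=0.6,
                         seed=11)


@pytest.fixture()
def toy_sumstats():
    rng = np.random.default_rng(0)
    m = 50
    z = rng.standard_normal(m)
    return pd.DataFrame({
        "SNP": [f"rs{i}" for i in range(m)],
        "CHR": 1, "BP": np.arange(1, m + 1) * 1000,
        "A1": "A", "A2": "G",
        "BETA": z * 0.01, "SE": 0.01,
        "P": 1.0, "N": 10000.0,
        "FREQ": 0.3,
    })
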