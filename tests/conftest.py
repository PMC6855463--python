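import numpy as np
import pytest

from clonegs import markers, pheno, simdata


@pytest.fixture(scope="session")
def small_panel():
    """Panmictic panel with a purely additive trait and 3-rep RCBD trials."""
    cfg = simdata.SimulationConfig(
        n_clusters=1,
        n_per_cluster=(150,),
        fst=0.0,
        n_markers=600,
        n_qtl=60,
        h2_additive=0.4,
        nonadditive_fraction=0.0,
        missing_rate=0.05,
        trial_layouts=[("RCBD", 3, "locA", 2011), ("RCBD", 3, "locA", 2012)],
        seed=101,
    )
    geno, trials, truth = simdata.simulate_study(cfg)
    return cfg, geno, trials, truth


@pytest.fixture(scope="session")
def small_panel_qc(small_panel):
    _, geno, _, _ = small_panel
    return markers.qc_pipeline(geno)


@pytest.fixture(scope="session")
def small_estimates(small_panel):
    _, _, trials, _ = small_panel
    return pheno.fit_clonal_lmm(trials, "trait_1")


@pytest.fixture(scope="session")
def structured_panel():
    """Two well-separated clusters (Fst 0.3) with an additive trait."""
    cfg = simdata.SimulationConfig(
        n_clusters=2,
        n_per_cluster=(50, 50),
        fst=0.30,
        n_markers=500,
        n_qtl=50,
        h2_additive=0.4,
        nonadditive_fraction=0.0,
        missing_rate=0.05,
        trial_layouts=[("RCBD", 3, "locA", 2011)],
        seed=202,
    )
    geno, trials, truth = simdata.simulate_study(cfg)
    return cfg, geno, trials, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
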