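import pytest

from epireg.simulate import SimConfig, simulate_cohort, simulate_drug_panel


@pytest.fixture(scope="session")
def std_cohort():
    """The standard synthetic study conditions: 200 samples, 300 planted
    pairs per layer at r = -0.5, four subtypes at delta = 1.5 SD."""
    cfg = SimConfig(seed=1)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def std_drug_panel(std_cohort):
    cfg, (_mrna, _mirna, _meth, _annot, _lists, _surv, truth) = std_cohort
    return simulate_drug_panel(cfg, truth.labels)


@pytest.fixture()
def small_cohort():
    """A fast, deliberately tiny cohort for structural tests."""
    cfg = SimConfig(seed=11, n_samples=60, n_genes=200, n_cpgs=60,
                    n_mirnas=40, n_true_met_pairs=20, n_true_mir_pairs=20,
                    de_genes_per_subtype=10, decoys_per_list=30)
    return cfg, simulate_cohort(cfg)
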