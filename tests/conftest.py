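import pytest

from ploidyscope import synthetic


@pytest.fixture(scope="session")
def day2_events():
    """Day-2 preset event table at the study conditions (n=10^4, cv=0.06)."""
    cfg = synthetic.FucciSimConfig(
        n_cells=10_000,
        class_probs=synthetic.DAY2_PRESET.class_probs,
        dna_cv=0.06,
        doublet_rate=0.05,
        induction_rate=0.9,
        seed=20,
    )
    return cfg, synthetic.simulate_fucci_events(cfg)


@pytest.fixture(scope="session")
def noise_free_events():
    """Singlet, fully induced, noise-free mixture covering every class."""
    cfg = synthetic.FucciSimConfig(
        n_cells=20_000,
        class_probs=synthetic.DAY2_PRESET.class_probs,
        dna_cv=0.0,
        doublet_rate=0.0,
        induction_rate=1.0,
        seed=3,
    )
    return cfg, synthetic.simulate_fucci_events(cfg)
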