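"""Generators: determinism, marginal frequencies, degenerate cases."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ploidyscope import synthetic
from ploidyscope.errors import ConfigError
from ploidyscope.synthetic import (
    ChipSimConfig,
    ConfettiSimConfig,
    DecaySimConfig,
    FucciSimConfig,
    NucleiSimConfig,
    simulate_chip,
    simulate_confetti,
    simulate_decay,
    simulate_fucci_events,
    simulate_nuclei,
)


@pytest.mark.parametrize(
    "factory",
    [
        lambda s: simulate_fucci_events(FucciSimConfig(n_cells=2000, doublet_rate=0.05, seed=s)),
        lambda s: simulate_confetti(ConfettiSimConfig(n_cells=2000, seed=s)),
        lambda s: simulate_nuclei(NucleiSimConfig(n_nuclei=300, seed=s)),
        lambda s: simulate_chip(ChipSimConfig(noise_sd=0.2, seed=s)),
    ],
    ids=["fucci", "confetti", "nuclei", "chip"],
)
def test_generators_deterministic_given_seed(factory):
    pd.testing.assert_frame_equal(factory(11), factory(11))
    assert not factory(11).equals(factory(12))


def test_decay_deterministic_given_seed():
    a, b = simulate_decay(DecaySimConfig(seed=5)), simulate_decay(DecaySimConfig(seed=5))
    np.testing.assert_array_equal(a.fluorescence, b.fluorescence)


@pytest.mark.parametrize(
    "bad",
    [
        dict(n_cells=-5),
        dict(class_probs=(0.5, 0.5, 0.0, 0.0, 0.0, 0.1)),  # sums to 1.1
        dict(doublet_rate=1.2),
        dict(induction_rate=-0.1),
        dict(dna_cv=-0.01),
    ],
)
def test_fucci_config_rejects_invalid(bad):
    with pytest.raises(ConfigError):
        FucciSimConfig(**bad)


def test_degenerate_diploid_g1_noise_free_is_exact():
    """All mass on diploid G1 with cv=0: every event mCherry+ at exactly 2C."""
    cfg = FucciSimConfig(
        n_cells=500,
        class_probs=(0, 1, 0, 0, 0, 0),
        dna_cv=0.0,
        induction_rate=1.0,
        seed=1,
    )
    ev = simulate_fucci_events(cfg)
    assert (ev["dna"] == 2 * cfg.gain).all()
    assert (ev["mcherry"] > 10 * cfg.reporter_background).all()
    assert (ev["mvenus"] < cfg.reporter_high / 10).all()
    assert (ev["true_class"] == "diploid_G1").all()


def test_fucci_class_frequencies_match_probs():
    """Chi-square goodness of fit of singlet class counts at n=1e5."""
    cfg = FucciSimConfig(n_cells=100_000, seed=42)
    counts = simulate_fucci_events(cfg)["true_class"].value_counts()
    observed = np.array([counts.get(c, 0) for c in synthetic.FUCCI_CLASSES])
    expected = np.asarray(cfg.class_probs) * observed.sum()
    assert stats.chisquare(observed, expected).pvalue > 0.01


def test_doublet_rate_recovered_from_truth_labels():
    cfg = FucciSimConfig(n_cells=10_000, doublet_rate=0.1, seed=8)
    ev = simulate_fucci_events(cfg)
    frac = ev["is_doublet"].mean()
    sd = np.sqrt(0.1 * 0.9 / len(ev))
    assert abs(frac - 0.1) < 3 * sd
    # doublets carry summed DNA and ~doubled pulse width
    assert ev.loc[ev["is_doublet"], "width"].min() > ev.loc[~ev["is_doublet"], "width"].max() * 1.3


def test_dead_events_lie_below_2c():
    cfg = FucciSimConfig(n_cells=20_000, class_probs=(1, 0, 0, 0, 0, 0), dna_cv=0.0, seed=2)
    dna_c = simulate_fucci_events(cfg)["dna"] / cfg.gain
    assert dna_c.between(0.5, 1.8).all()


def test_non_induced_cells_have_background_reporters():
    cfg = FucciSimConfig(n_cells=5000, induction_rate=0.5, seed=9)
    ev = simulate_fucci_events(cfg)
    off = ev[~ev["induced"]]
    assert len(off) > 1000
    assert (off[["mcherry", "mvenus"]] < 100).all().all()


class TestConfettiGenerator:
    def test_bicoloured_two_thirds_among_polyploid(self):
        cfg = ConfettiSimConfig(
            n_cells=30_000,
            polyploid_fraction=1.0,
            induction_efficiency=1.0,
            colour_probs=(1 / 3, 1 / 3, 1 / 3, 0.0),
            seed=13,
        )
        cells = simulate_confetti(cfg)
        bicol = (cells["colour1"] != cells["colour2"]).mean()
        sd = np.sqrt((2 / 3) * (1 / 3) / len(cells))
        assert abs(bicol - 2 / 3) < 3 * sd
        assert abs((1 - bicol) - 1 / 3) < 3 * sd

    def test_diploid_cells_never_bicoloured(self):
        cfg = ConfettiSimConfig(n_cells=2000, polyploid_fraction=0.0, seed=3)
        cells = simulate_confetti(cfg)
        assert (cells["colour2"] == "").all()

    def test_closed_form_expectation_p_times_two_thirds(self):
        cfg = ConfettiSimConfig(
            n_cells=100_000,
            polyploid_fraction=0.3,
            induction_efficiency=1.0,
            colour_probs=(1 / 3, 1 / 3, 1 / 3, 0.0),
            seed=14,
        )
        cells = simulate_confetti(cfg)
        bicol = ((cells["colour2"] != "") & (cells["colour1"] != cells["colour2"])).mean()
        expected = 0.3 * 2 / 3
        sd = np.sqrt(expected * (1 - expected) / len(cells))
        assert abs(bicol - expected) < 4 * sd

    def test_rejects_invalid_colour_probs(self):
        with pytest.raises(ConfigError):
            ConfettiSimConfig(colour_probs=(0.5, 0.5, 0.5, 0.0))


class TestNucleiGenerator:
    def test_noise_free_linear_intensities(self):
        cfg = NucleiSimConfig(
            n_nuclei=100,
            ploidy_mix=(0.0, 1.0, 0.0),
            gain=100.0,
            background_mean=0.0,
            background_sd=0.0,
            noise_cv=0.0,
            n_reference=20,
            seed=4,
        )
        nuc = simulate_nuclei(cfg)
        assert (nuc.loc[nuc["reference_diploid"], "intensity"] == 200.0).all()
        assert (nuc.loc[~nuc["reference_diploid"], "intensity"] == 400.0).all()

    def test_marker_effect_shifts_positive_nuclei(self):
        cfg = NucleiSimConfig(
            n_nuclei=600,
            ploidy_mix=(0.95, 0.05, 0.0),
            marker_positive_mix=(0.4, 0.5, 0.1),
            seed=5,
        )
        nuc = simulate_nuclei(cfg)
        body = nuc[~nuc["reference_diploid"]]
        assert body.groupby("marker_positive")["true_c"].mean().loc[True] > \
            body.groupby("marker_positive")["true_c"].mean().loc[False]

    def test_rejects_nonpositive_gain(self):
        with pytest.raises(ConfigError):
            NucleiSimConfig(gain=0.0)


class TestDecayGenerator:
    def test_halflife_definition_noise_free(self):
        """Mono-exponential: intensity at t = t_half is half the start value."""
        # t_half = 30 min <=> gfr = 14616.8 / 30 * bw / 100
        bw = 25.0
        gfr = synthetic.GFR_CONVERSION_UL / 30.0 * bw / 100.0
        cfg = DecaySimConfig(
            gfr_true=gfr, body_weight=bw, distribution_weight=0.0,
            noise_sd=0.0, sampling_interval=1.0, duration=60.0, seed=0,
        )
        assert cfg.elimination_halflife == pytest.approx(30.0)
        curve = simulate_decay(cfg)
        f = dict(zip(curve.time, curve.fluorescence))
        assert f[30.0] == pytest.approx(f[0.0] / 2)

    def test_embedded_halflife_inverts_gfr_formula(self):
        cfg = DecaySimConfig(gfr_true=250.0, body_weight=25.0)
        assert cfg.elimination_halflife == pytest.approx(14616.8 / 250.0 * 25.0 / 100.0)
        assert cfg.elimination_halflife == pytest.approx(14.6168)

    def test_rejects_nonpositive_gfr(self):
        with pytest.raises(ConfigError):
            DecaySimConfig(gfr_true=0.0)


def test_chip_generator_embeds_true_enrichment():
    from ploidyscope import physio

    cfg = ChipSimConfig(true_fr=6.0, noise_sd=0.0, seed=1)
    table = simulate_chip(cfg)
    spec = table[table["antibody"] == "specific"].iloc[0]
    igg = table[table["antibody"] == "IgG"].iloc[0]
    fr = physio.chip_fold_enrichment(
        physio.ChipSample(spec["ct_bound"], spec["ct_input"], spec["dilution_factor"]),
        physio.ChipSample(igg["ct_bound"], igg["ct_input"], igg["dilution_factor"], "IgG"),
    )
    assert fr == pytest.approx(6.0)
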