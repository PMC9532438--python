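"""Confetti combinatorics, efficiency correction, estimator behaviour."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ploidyscope import synthetic
from ploidyscope.confetti import (
    ConfettiTally,
    correct_for_efficiency,
    estimate_polyploid_fraction,
    expected_tally,
    p_bicoloured,
    tally_confetti,
)
from ploidyscope.errors import ConfigError, DataError
from ploidyscope.synthetic import ConfettiSimConfig, simulate_confetti


def _enumerate_pair_outcomes(probs):
    """Brute-force oracle: exact outcome masses over all ordered colour pairs."""
    duplicate = sum(p * p for p in probs)
    bicoloured = sum(
        probs[i] * probs[j]
        for i, j in itertools.product(range(len(probs)), repeat=2)
        if i != j
    )
    return duplicate, bicoloured


class TestPBicoloured:
    @pytest.mark.parametrize("n, expected", [(2, 1 / 2), (3, 2 / 3), (4, 3 / 4)])
    def test_equiprobable_discordance(self, n, expected):
        assert p_bicoloured(n) == pytest.approx(expected)
        # cross-check against pair enumeration
        _, bicol = _enumerate_pair_outcomes([1 / n] * n)
        assert p_bicoloured(n) == pytest.approx(bicol)

    def test_rejects_fewer_than_two_colours(self):
        with pytest.raises(ConfigError):
            p_bicoloured(1)


class TestEfficiencyCorrection:
    def test_published_normalisation(self):
        """13.3% bi-coloured at 84.7% efficiency corrects to 15.7%."""
        assert round(correct_for_efficiency(13.3, 0.847), 1) == 15.7

    def test_identity_at_full_efficiency(self):
        assert correct_for_efficiency(10.0, 1.0) == 10.0

    def test_half_efficiency_doubles(self):
        assert correct_for_efficiency(10.0, 0.5) == 20.0

    def test_rejects_zero_efficiency(self):
        with pytest.raises(ConfigError):
            correct_for_efficiency(10.0, 0.0)

    @given(b=st.floats(0.0, 50.0), e=st.floats(0.1, 1.0))
    @settings(derandomize=True, max_examples=100)
    def test_scale_equivariance(self, b, e):
        assert correct_for_efficiency(2 * b, e) == pytest.approx(
            2 * correct_for_efficiency(b, e))


class TestExpectedTally:
    def test_equal_colours_no_gfp_gives_two_thirds(self):
        cfg = ConfettiSimConfig(
            polyploid_fraction=1.0, colour_probs=(1 / 3, 1 / 3, 1 / 3, 0.0))
        exp = expected_tally(cfg)
        assert exp.bicoloured == pytest.approx(2 / 3)
        assert exp.mono_duplicate == pytest.approx(1 / 3)

    def test_no_polyploids_no_bicoloured(self):
        cfg = ConfettiSimConfig(polyploid_fraction=0.0)
        assert expected_tally(cfg).bicoloured == 0.0

    def test_outcome_fractions_sum_to_one(self):
        cfg = ConfettiSimConfig(
            polyploid_fraction=0.37, colour_probs=(0.4, 0.3, 0.28, 0.02))
        assert sum(expected_tally(cfg).outcome_fractions().values()) == pytest.approx(1.0)

    def test_matches_pair_enumeration_with_rare_gfp(self):
        """p=0.2 with GFP=0.01: bi-coloured mass equals the 16-pair enumeration."""
        probs = (0.33, 0.33, 0.33, 0.01)
        cfg = ConfettiSimConfig(polyploid_fraction=0.2, colour_probs=probs)
        exp = expected_tally(cfg)
        duplicate, bicoloured = _enumerate_pair_outcomes(probs)
        assert exp.bicoloured == pytest.approx(0.2 * bicoloured)
        assert exp.bicoloured == pytest.approx(0.2 * (1 - sum(p * p for p in probs)))
        assert exp.mono_duplicate == pytest.approx(0.2 * duplicate)

    @pytest.mark.parametrize("case", range(10))
    def test_simulation_agrees_with_closed_form(self, case):
        """Simulated outcome frequencies match expectations within 4 binomial SDs."""
        rng = np.random.default_rng(1000 + case)
        c = rng.dirichlet([5, 5, 5, 0.3])
        cfg = ConfettiSimConfig(
            n_cells=20_000,
            polyploid_fraction=float(rng.uniform(0.05, 0.9)),
            induction_efficiency=1.0,
            colour_probs=tuple(c),
            seed=case,
        )
        cells = simulate_confetti(cfg)
        exp = expected_tally(cfg)
        dup = ((cells["colour2"] != "") & (cells["colour1"] == cells["colour2"])).mean()
        bicol = ((cells["colour2"] != "") & (cells["colour1"] != cells["colour2"])).mean()
        for observed, expected in ((bicol, exp.bicoloured), (dup, exp.mono_duplicate)):
            sd = np.sqrt(max(expected * (1 - expected), 1e-12) / cfg.n_cells)
            assert abs(observed - expected) <= 4 * sd + 1e-9


class TestEstimator:
    def test_tally_invariants_enforced(self):
        with pytest.raises(DataError):
            ConfettiTally(n_total_tc=10, n_coloured=20, n_bicoloured=5)
        with pytest.raises(DataError):
            ConfettiTally(n_total_tc=10, n_coloured=5, n_bicoloured=-1)

    def test_zero_bicoloured_gives_zero_estimate(self):
        tally = ConfettiTally(n_total_tc=400, n_coloured=300, n_bicoloured=0)
        est = estimate_polyploid_fraction(tally, seed=0)
        assert est.p_hat == 0.0
        assert est.ci_low == 0.0

    def test_all_polyploid_boundary_clips_to_one(self):
        tally = ConfettiTally(n_total_tc=300, n_coloured=300, n_bicoloured=200)
        est = estimate_polyploid_fraction(tally, seed=0)
        assert est.p_hat == 1.0

    def test_zero_coloured_cells_raises(self):
        with pytest.raises(DataError):
            estimate_polyploid_fraction(
                ConfettiTally(n_total_tc=10, n_coloured=0, n_bicoloured=0), seed=0)

    def test_parameter_recovery_at_p030(self):
        """Tally from a p=0.30 simulation recovers p_hat in [0.28, 0.32]."""
        cfg = ConfettiSimConfig(
            n_cells=50_000, polyploid_fraction=0.30, induction_efficiency=1.0,
            colour_probs=(1 / 3, 1 / 3, 1 / 3, 0.0), seed=21)
        tally = tally_confetti(simulate_confetti(cfg))
        est = estimate_polyploid_fraction(tally, seed=21)
        assert 0.28 <= est.p_hat <= 0.32
        assert est.ci_low <= 0.30 <= est.ci_high

    def test_bias_shrinks_with_sample_size(self):
        """|bias| decreases over n = 1e3, 1e4, 1e5 and is < 0.01 at n=1e5."""
        biases = []
        for n in (1_000, 10_000, 100_000):
            errs = []
            for rep in range(20):
                cfg = ConfettiSimConfig(
                    n_cells=n, polyploid_fraction=0.2, induction_efficiency=1.0,
                    colour_probs=(1 / 3, 1 / 3, 1 / 3, 0.0), seed=rep * 37 + n)
                tally = tally_confetti(simulate_confetti(cfg))
                errs.append(tally.n_bicoloured / tally.n_coloured * 1.5 - 0.2)
            biases.append(abs(np.mean(errs)))
        assert biases[2] < 0.01
        assert biases[2] <= biases[0]

    def test_gfp_cells_excluded_from_both_sides(self):
        cells = simulate_confetti(ConfettiSimConfig(
            n_cells=30_000, polyploid_fraction=0.3, induction_efficiency=0.9,
            colour_probs=(0.3, 0.3, 0.3, 0.1), seed=6))
        tally = tally_confetti(cells)
        n_induced = int(cells["induced"].sum())
        assert tally.n_gfp_excluded > 0
        assert tally.n_coloured + tally.n_gfp_excluded == n_induced
        # scored bi-coloured fraction matches the conditional expectation
        exp = expected_tally(ConfettiSimConfig(
            polyploid_fraction=0.3, colour_probs=(0.3, 0.3, 0.3, 0.1)))
        b = tally.n_bicoloured / tally.n_coloured
        sd = np.sqrt(exp.bicoloured_given_scored * (1 - exp.bicoloured_given_scored)
                     / tally.n_coloured)
        assert abs(b - exp.bicoloured_given_scored) < 4 * sd

    def test_plug_in_discordance_mode(self):
        """Unequal colours: the 2/3 inversion is biased, the plug-in is not."""
        probs = (0.6, 0.2, 0.2, 0.0)
        cfg = ConfettiSimConfig(
            n_cells=50_000, polyploid_fraction=0.4, induction_efficiency=1.0,
            colour_probs=probs, seed=17)
        tally = tally_confetti(simulate_confetti(cfg))
        _, discordance = _enumerate_pair_outcomes(probs[:3])
        est = estimate_polyploid_fraction(tally, seed=17, pair_discordance=discordance)
        assert est.p_hat == pytest.approx(0.4, abs=0.02)
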