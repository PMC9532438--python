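"""Confetti recombination combinatorics and polyploidy estimation.

The Confetti (Brainbow-type) reporter stochastically fixes one fluorochrome
per recombination event.  A diploid cell recombines once and is
mono-coloured; a tetraploid (4C) cell recombines twice, independently, so
with three equiprobable scored colours (RFP, YFP, CFP) it is bi-coloured
with probability 2/3 and duplicate mono-coloured with probability 1/3.
GFP recombines rarely; GFP-containing cells are excluded from both
numerator and denominator of every scored fraction.

This module provides the closed-form outcome expectations, the efficiency
normalisation applied to observed bi-coloured percentages, and a
model-based estimator of the polyploid fraction,

    p_hat = b_obs / P(bi-coloured | polyploid) = (3/2) * b_obs,

with a percentile-bootstrap confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .synthetic import ConfettiSimConfig

__all__ = [
    "ConfettiTally",
    "ConfettiEstimate",
    "ConfettiExpectation",
    "p_bicoloured",
    "correct_for_efficiency",
    "estimate_polyploid_fraction",
    "expected_tally",
    "tally_confetti",
]


@dataclass(frozen=True)
class ConfettiTally:
    """Counts from one scored region (e.g. cortex, outer medulla).

    ``n_coloured`` counts Confetti+ cells after excluding the
    ``n_gfp_excluded`` GFP-containing ones; ``n_bicoloured`` counts the
    scored combinations RFP+YFP, RFP+CFP, YFP+CFP.
    """

    n_total_tc: int
    n_coloured: int
    n_bicoloured: int
    n_gfp_excluded: int = 0
    region: str = ""

    def __post_init__(self):
        counts = (self.n_total_tc, self.n_coloured, self.n_bicoloured, self.n_gfp_excluded)
        if any(c < 0 for c in counts):
            raise DataError("tally counts must be non-negative")
        if not self.n_bicoloured <= self.n_coloured <= self.n_total_tc:
            raise DataError(
                "tally must satisfy n_bicoloured <= n_coloured <= n_total_tc"
            )


@dataclass(frozen=True)
class ConfettiEstimate:
    """Polyploid-fraction estimate derived from a :class:`ConfettiTally`.

    ``b_corrected`` is the efficiency-normalised bi-coloured percentage
    (``b_obs / efficiency``, reported in percent); ``p_hat`` is the
    model-based polyploid fraction ``(3/2) * b_obs`` clipped to [0, 1],
    with a 95% percentile-bootstrap interval.
    """

    b_obs: float
    efficiency: float
    b_corrected: float
    p_hat: float
    ci_low: float
    ci_high: float


def p_bicoloured(n_colours: int) -> float:
    """Probability that two independent uniform colour draws differ.

    With ``n`` equiprobable colours this is ``(n - 1) / n``; for the three
    scored Confetti colours it is 2/3 (and 1/3 of polyploid cells duplicate
    a colour, becoming indistinguishable from diploids).
    """
    if n_colours < 2:
        raise ConfigError("n_colours must be >= 2")
    return (n_colours - 1) / n_colours


def correct_for_efficiency(b_obs_pct: float, efficiency: float) -> float:
    """Normalise an observed bi-coloured percentage by recombination efficiency.

    ``efficiency`` is the fraction of tubular cells in which the reporter
    recombined (Confetti+ over total).  Returns ``b_obs_pct / efficiency``,
    reproducing the published normalisation (13.3% at 84.7% efficiency
    gives 15.7%).
    """
    if not 0.0 < efficiency <= 1.0:
        raise ConfigError("efficiency must lie in (0, 1]")
    if b_obs_pct < 0:
        raise ConfigError("b_obs_pct must be non-negative")
    return b_obs_pct / efficiency


def estimate_polyploid_fraction(
    tally: ConfettiTally,
    n_bootstrap: int = 2000,
    seed: int | None = None,
    pair_discordance: float | None = None,
) -> ConfettiEstimate:
    """Estimate the polyploid fraction from a Confetti tally.

    The point estimate inverts the bi-coloured probability:
    ``p_hat = b_obs / pair_discordance`` clipped to [0, 1], where
    ``pair_discordance`` defaults to 2/3 (three equiprobable colours).  The
    95% CI is a percentile bootstrap over the ``n_coloured`` scored cells
    (Bernoulli resampling of the bi-coloured indicator), seeded.

    Raises :class:`DataError` when no coloured cell was scored.
    """
    if tally.n_coloured == 0:
        raise DataError("cannot estimate polyploid fraction from zero coloured cells")
    if pair_discordance is None:
        pair_discordance = p_bicoloured(3)
    if not 0.0 < pair_discordance <= 1.0:
        raise ConfigError("pair_discordance must lie in (0, 1]")

    b_obs = tally.n_bicoloured / tally.n_coloured
    efficiency = tally.n_coloured / tally.n_total_tc if tally.n_total_tc else np.nan
    p_hat = min(b_obs / pair_discordance, 1.0)

    rng = np.random.default_rng(seed)
    b_boot = rng.binomial(tally.n_coloured, b_obs, size=n_bootstrap) / tally.n_coloured
    p_boot = np.minimum(b_boot / pair_discordance, 1.0)
    ci_low, ci_high = np.quantile(p_boot, [0.025, 0.975])

    return ConfettiEstimate(
        b_obs=b_obs,
        efficiency=float(efficiency),
        b_corrected=correct_for_efficiency(100.0 * b_obs, efficiency)
        if np.isfinite(efficiency) and efficiency > 0
        else np.nan,
        p_hat=float(p_hat),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
    )


@dataclass(frozen=True)
class ConfettiExpectation:
    """Closed-form outcome fractions among induced cells."""

    mono_single: float  # diploid, one colour
    mono_duplicate: float  # polyploid, same colour twice
    bicoloured: float  # polyploid, two distinct colours (any, incl. GFP)
    gfp_containing: float  # any draw fixed GFP (excluded from scoring)
    bicoloured_given_scored: float  # among non-GFP coloured cells

    def outcome_fractions(self) -> dict:
        """The three exhaustive outcome classes (sum to 1)."""
        return {
            "mono_single": self.mono_single,
            "mono_duplicate": self.mono_duplicate,
            "bicoloured": self.bicoloured,
        }


def expected_tally(cfg: ConfettiSimConfig) -> ConfettiExpectation:
    """Exact multinomial expectations for a Confetti configuration.

    With colour probabilities ``c`` and polyploid fraction ``p`` (among
    induced cells): duplicate mono-colour mass is ``p * sum(c_i^2)``,
    bi-coloured mass ``p * (1 - sum(c_i^2))``, and diploid mono-colour mass
    ``1 - p``.  GFP accounting follows the exclusion rule used in scoring.
    """
    c = np.asarray(cfg.colour_probs, dtype=float)
    p = cfg.polyploid_fraction
    sum_sq = float(np.sum(c * c))

    c_gfp = c[3]
    # a diploid contains GFP iff its single draw is GFP; a polyploid iff
    # either of its two draws is
    gfp_containing = (1 - p) * c_gfp + p * (1.0 - (1.0 - c_gfp) ** 2)

    c_scored = c[:3]
    bicol_non_gfp = p * float(np.sum(c_scored) ** 2 - np.sum(c_scored**2))
    scored = 1.0 - gfp_containing
    return ConfettiExpectation(
        mono_single=1.0 - p,
        mono_duplicate=p * sum_sq,
        bicoloured=p * (1.0 - sum_sq),
        gfp_containing=gfp_containing,
        bicoloured_given_scored=bicol_non_gfp / scored if scored > 0 else np.nan,
    )


def tally_confetti(cells: pd.DataFrame, region: str = "") -> ConfettiTally:
    """Reduce a per-cell colour table to a scored :class:`ConfettiTally`.

    ``cells`` must carry ``colour1``, ``colour2`` (empty string when
    absent) and ``induced`` columns, as produced by
    :func:`ploidyscope.synthetic.simulate_confetti`.  GFP-containing cells
    are excluded from ``n_coloured`` and counted in ``n_gfp_excluded``.
    """
    colour1 = cells["colour1"].to_numpy(dtype=object)
    colour2 = cells["colour2"].to_numpy(dtype=object)
    induced = cells["induced"].to_numpy(dtype=bool)

    coloured = induced & (colour1 != "")
    has_gfp = coloured & ((colour1 == "GFP") | (colour2 == "GFP"))
    scored = coloured & ~has_gfp
    bicol = scored & (colour2 != "") & (colour1 != colour2)

    return ConfettiTally(
        n_total_tc=len(cells),
        n_coloured=int(scored.sum()),
        n_bicoloured=int(bicol.sum()),
        n_gfp_excluded=int(has_gfp.sum()),
        region=region,
    )
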