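"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (FUCCI gating, Confetti polyploidy
estimation, PicoGreen ploidy calls, GFR half-life fitting, ChIP-qPCR
enrichment) consumes tables produced here, so the whole toolkit is testable
without any instrument export.  Each generator is deterministic given its
seed and emits ground-truth columns alongside the observable ones.

Conventions
-----------
* DNA content is expressed in C-units (haploid genome equivalents); a
  diploid G1 cell is 2C.  The stain intensity of a singlet is
  ``gain * C * lognormal(1, cv)``, i.e. multiplicative noise with unit mean.
* Reporter channels (mCherry = G1, mVenus = S/G2/M, both = G1/S boundary)
  are two-level: a bright "expressed" level and a dim autofluorescence
  background, each with its own lognormal spread.
* Dead/dying events carry sub-2C DNA (uniform in 0.5C-1.8C) but S/G2/M-type
  reporter states, mirroring the observation that tubular-cell death after
  ischemic injury happens out of G1.
* Doublets are sums of two singlets with summed pulse width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "FUCCI_CLASSES",
    "TRUE_CALL_OF_CLASS",
    "FucciSimConfig",
    "ConfettiSimConfig",
    "NucleiSimConfig",
    "DecaySimConfig",
    "ChipSimConfig",
    "DAY2_PRESET",
    "DAY3_PRESET",
    "HEALTHY_PRESET",
    "simulate_fucci_events",
    "simulate_confetti",
    "simulate_nuclei",
    "simulate_decay",
    "simulate_chip",
    "GFR_CONVERSION_UL",
]

# Empirical conversion constant of the transcutaneous FITC-sinistrin device
# (microlitres); GFR [ul/min] = GFR_CONVERSION_UL / t_half [min] * bw [g] / 100.
GFR_CONVERSION_UL = 14616.8

FUCCI_CLASSES = (
    "dead",
    "diploid_G1",
    "diploid_cycling",
    "polyploid_4C_G1",
    "polyploid_cycling_4C",
    "polyploid_cycling_8C",
)

#: The call an ideal gate should produce for each generator class.
TRUE_CALL_OF_CLASS = {
    "dead": "dead",
    "diploid_G1": "diploid_G1",
    "diploid_cycling": "cycling",
    "polyploid_4C_G1": "polyploid_noncycling",
    "polyploid_cycling_4C": "polyploid_cycling",
    "polyploid_cycling_8C": "polyploid_cycling",
}

CONFETTI_COLOURS = ("RFP", "YFP", "CFP", "GFP")


def _check_probs(p, n, what):
    p = np.asarray(p, dtype=float)
    if p.shape != (n,):
        raise ConfigError(f"{what} must have length {n}, got shape {p.shape}")
    if np.any(p < 0) or np.any(p > 1):
        raise ConfigError(f"{what} entries must lie in [0, 1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ConfigError(f"{what} must sum to 1 (got {p.sum():.12g})")
    return p


def _check_rate(x, name):
    if not 0.0 <= x <= 1.0:
        raise ConfigError(f"{name} must lie in [0, 1], got {x}")


def _lognormal_factor(rng, cv, size):
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    mu = -0.5 * sigma * sigma
    return rng.lognormal(mu, sigma, size)


# --------------------------------------------------------------------------
# FUCCI flow-cytometry events
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FucciSimConfig:
    """Mixture of ploidy x cell-cycle classes measured as flow events.

    ``class_probs`` orders classes as :data:`FUCCI_CLASSES`.  ``gain`` is the
    DNA-stain intensity of one C-unit, so the diploid G1 peak sits at
    ``2 * gain``.
    """

    n_cells: int = 10_000
    class_probs: tuple = (0.05, 0.60, 0.25, 0.05, 0.03, 0.02)
    dna_cv: float = 0.06
    doublet_rate: float = 0.0
    induction_rate: float = 1.0
    seed: int = 0
    gain: float = 100.0
    reporter_high: float = 1000.0
    reporter_background: float = 10.0
    reporter_cv: float = 0.25
    width_mean: float = 70.0
    width_cv: float = 0.05

    def __post_init__(self):
        if self.n_cells <= 0:
            raise ConfigError("n_cells must be positive")
        _check_probs(self.class_probs, len(FUCCI_CLASSES), "class_probs")
        if self.dna_cv < 0:
            raise ConfigError("dna_cv must be >= 0")
        _check_rate(self.doublet_rate, "doublet_rate")
        _check_rate(self.induction_rate, "induction_rate")
        if self.gain <= 0:
            raise ConfigError("gain must be positive")


# Class compositions echoing the reported tubular-cell distributions after
# ischemia-reperfusion injury: at day 2 ~39.8% of cells are cycling; by day 3
# ~17% have become polyploid and ~19.6% have died; healthy kidneys are almost
# entirely diploid G1.
DAY2_PRESET = FucciSimConfig(
    class_probs=(0.052, 0.500, 0.398, 0.020, 0.020, 0.010),
)
DAY3_PRESET = FucciSimConfig(
    class_probs=(0.196, 0.546, 0.088, 0.100, 0.050, 0.020),
)
HEALTHY_PRESET = FucciSimConfig(
    class_probs=(0.010, 0.940, 0.020, 0.020, 0.005, 0.005),
)


def _singlet_fields(rng, cfg, n):
    """Draw class, true DNA (C-units), reporter state for n singlets."""
    cls_idx = rng.choice(len(FUCCI_CLASSES), size=n, p=np.asarray(cfg.class_probs))
    c_value = np.empty(n)
    # reporter state codes: 0 = mCherry only, 1 = mVenus only, 2 = both
    reporter = np.empty(n, dtype=int)
    coin = rng.random(n)

    for i, name in enumerate(FUCCI_CLASSES):
        m = cls_idx == i
        k = int(m.sum())
        if k == 0:
            continue
        if name == "dead":
            c_value[m] = rng.uniform(0.5, 1.8, k)
            reporter[m] = np.where(coin[m] < 0.5, 1, 2)
        elif name == "diploid_G1":
            c_value[m] = 2.0
            reporter[m] = 0
        elif name == "diploid_cycling":
            # half at the G1/S boundary (double-positive, 2C), half in
            # S/G2/M (mVenus only, DNA between 2C and 4C)
            boundary = coin[m] < 0.5
            cc = np.where(boundary, 2.0, 0.0)
            cc[~boundary] = rng.uniform(2.0, 4.0, int((~boundary).sum()))
            c_value[m] = cc
            reporter[m] = np.where(boundary, 2, 1)
        elif name == "polyploid_4C_G1":
            c_value[m] = 4.0
            reporter[m] = 0
        elif name == "polyploid_cycling_4C":
            c_value[m] = 4.0
            reporter[m] = 2
        else:  # polyploid_cycling_8C
            c_value[m] = 8.0
            reporter[m] = np.where(coin[m] < 0.5, 1, 2)

    dna = cfg.gain * c_value * _lognormal_factor(rng, cfg.dna_cv, n)
    width = cfg.width_mean * _lognormal_factor(rng, cfg.width_cv, n)
    return cls_idx, dna, reporter, width


def _reporter_intensity(rng, cfg, on_mask):
    n = on_mask.size
    level = np.where(on_mask, cfg.reporter_high, cfg.reporter_background)
    return level * _lognormal_factor(rng, cfg.reporter_cv, n)


def simulate_fucci_events(cfg: FucciSimConfig) -> pd.DataFrame:
    """Simulate a FUCCI2aR flow-cytometry event table.

    Returns a frame with columns ``event_id, mcherry, mvenus, dna, width,
    true_class, is_doublet, induced``.  ``true_class`` is the generator class
    for singlets and ``"doublet"`` for doublet events.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells

    is_doublet = rng.random(n) < cfg.doublet_rate
    n_dbl = int(is_doublet.sum())

    cls_idx, dna, reporter, width = _singlet_fields(rng, cfg, n)
    induced = rng.random(n) < cfg.induction_rate

    # doublets: pair the event with an extra independent singlet
    if n_dbl:
        _, dna2, rep2, width2 = _singlet_fields(rng, cfg, n_dbl)
        ind2 = rng.random(n_dbl) < cfg.induction_rate
        dna[is_doublet] = dna[is_doublet] + dna2
        width[is_doublet] = width[is_doublet] + width2
        # the measured reporter state of a doublet is the union of its cells
        r1 = reporter[is_doublet]
        both = (r1 != rep2) | (r1 == 2)
        reporter[is_doublet] = np.where(both, 2, r1)
        induced[is_doublet] = induced[is_doublet] | ind2

    mch_on = induced & ((reporter == 0) | (reporter == 2))
    mv_on = induced & ((reporter == 1) | (reporter == 2))
    mcherry = _reporter_intensity(rng, cfg, mch_on)
    mvenus = _reporter_intensity(rng, cfg, mv_on)

    true_class = np.array(FUCCI_CLASSES, dtype=object)[cls_idx]
    true_class[is_doublet] = "doublet"

    return pd.DataFrame(
        {
            "event_id": np.arange(n),
            "mcherry": mcherry,
            "mvenus": mvenus,
            "dna": dna,
            "width": width,
            "true_class": true_class,
            "is_doublet": is_doublet,
            "induced": induced,
        }
    )


# --------------------------------------------------------------------------
# Confetti stochastic recombination
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfettiSimConfig:
    """Stochastic multicolour reporter recombination.

    A diploid cell fixes one colour; a 4C polyploid cell fixes two
    independent colours, so with three equiprobable colours 2/3 of polyploid
    cells are bi-coloured.  GFP recombines rarely and GFP-containing cells
    are excluded from scoring downstream.
    """

    n_cells: int = 10_000
    polyploid_fraction: float = 0.15
    induction_efficiency: float = 0.847
    colour_probs: tuple = (0.33, 0.33, 0.33, 0.01)  # RFP, YFP, CFP, GFP
    seed: int = 0

    def __post_init__(self):
        if self.n_cells <= 0:
            raise ConfigError("n_cells must be positive")
        _check_rate(self.polyploid_fraction, "polyploid_fraction")
        _check_rate(self.induction_efficiency, "induction_efficiency")
        _check_probs(self.colour_probs, 4, "colour_probs")


def simulate_confetti(cfg: ConfettiSimConfig) -> pd.DataFrame:
    """Simulate per-cell Confetti colour outcomes.

    Returns columns ``cell_id, colour1, colour2, induced, true_polyploid``;
    ``colour2`` is empty for diploid cells and ``colour1``/``colour2`` are
    empty for non-induced cells.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    polyploid = rng.random(n) < cfg.polyploid_fraction
    induced = rng.random(n) < cfg.induction_efficiency
    probs = np.asarray(cfg.colour_probs)

    draw1 = rng.choice(4, size=n, p=probs)
    draw2 = rng.choice(4, size=n, p=probs)

    colours = np.array(CONFETTI_COLOURS, dtype=object)
    colour1 = np.where(induced, colours[draw1], "")
    colour2 = np.where(induced & polyploid, colours[draw2], "")

    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "colour1": colour1,
            "colour2": colour2,
            "induced": induced,
            "true_polyploid": polyploid,
        }
    )


# --------------------------------------------------------------------------
# PicoGreen nuclear intensities
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleiSimConfig:
    """Per-nucleus PicoGreen intensities over background.

    ``ploidy_mix`` gives the probabilities of C-classes (2C, 4C, 8C) for
    marker-negative nuclei; ``marker_positive_mix`` overrides it for
    marker-positive (e.g. YAP1+) nuclei.  A separate pool of
    ``n_reference`` diploid nuclei plays the role of the healthy-biopsy
    internal calibration control.
    """

    n_nuclei: int = 200
    ploidy_mix: tuple = (0.90, 0.08, 0.02)
    gain: float = 100.0
    background_mean: float = 50.0
    background_sd: float = 5.0
    noise_cv: float = 0.06
    marker_positive_fraction: float = 0.5
    marker_positive_mix: tuple | None = None
    n_reference: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_nuclei <= 0:
            raise ConfigError("n_nuclei must be positive")
        if self.gain <= 0:
            raise ConfigError("gain must be positive")
        _check_probs(self.ploidy_mix, 3, "ploidy_mix")
        if self.marker_positive_mix is not None:
            _check_probs(self.marker_positive_mix, 3, "marker_positive_mix")
        _check_rate(self.marker_positive_fraction, "marker_positive_fraction")
        if self.background_sd < 0 or self.noise_cv < 0:
            raise ConfigError("background_sd and noise_cv must be >= 0")


_C_CLASSES = np.array([2.0, 4.0, 8.0])


def simulate_nuclei(cfg: NucleiSimConfig) -> pd.DataFrame:
    """Simulate a per-nucleus intensity table.

    Columns: ``nucleus_id, intensity, background, marker_positive, tubular,
    reference_diploid, true_c``.  ``background`` is the local background the
    measurement software would report; ``intensity`` includes it.
    """
    rng = np.random.default_rng(cfg.seed)
    n_ref = cfg.n_reference
    n = cfg.n_nuclei + n_ref

    marker = np.zeros(n, dtype=bool)
    marker[n_ref:] = rng.random(cfg.n_nuclei) < cfg.marker_positive_fraction
    reference = np.zeros(n, dtype=bool)
    reference[:n_ref] = True

    c_value = np.empty(n)
    c_value[:n_ref] = 2.0
    neg_mix = np.asarray(cfg.ploidy_mix)
    pos_mix = np.asarray(
        cfg.marker_positive_mix if cfg.marker_positive_mix is not None else cfg.ploidy_mix
    )
    body = slice(n_ref, n)
    idx = np.empty(cfg.n_nuclei, dtype=int)
    m = marker[body]
    idx[m] = rng.choice(3, size=int(m.sum()), p=pos_mix)
    idx[~m] = rng.choice(3, size=int((~m).sum()), p=neg_mix)
    c_value[body] = _C_CLASSES[idx]

    background = (
        cfg.background_mean + rng.normal(0.0, cfg.background_sd, n)
        if cfg.background_sd > 0
        else np.full(n, cfg.background_mean)
    )
    signal = cfg.gain * c_value * _lognormal_factor(rng, cfg.noise_cv, n)
    return pd.DataFrame(
        {
            "nucleus_id": np.arange(n),
            "intensity": background + signal,
            "background": background,
            "marker_positive": marker,
            "tubular": np.ones(n, dtype=bool),
            "reference_diploid": reference,
            "true_c": c_value,
        }
    )


# --------------------------------------------------------------------------
# FITC-sinistrin decay curves
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DecaySimConfig:
    """Two-compartment transcutaneous FITC-sinistrin kinetics.

    The elimination half-life is derived from the target GFR by inverting
    the device formula ``GFR = 14616.8 / t_half * bw / 100``; the fast
    distribution compartment has half-life ``distribution_halflife`` and
    carries ``distribution_weight`` of the initial amplitude.
    """

    gfr_true: float = 250.0  # ul/min
    body_weight: float = 25.0  # g
    sampling_interval: float = 0.5  # min
    duration: float = 90.0  # min
    distribution_halflife: float = 2.0  # min
    distribution_weight: float = 0.25
    noise_sd: float = 0.003  # additive, in units of the initial amplitude
    amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.gfr_true <= 0:
            raise ConfigError("gfr_true must be positive")
        if self.body_weight <= 0:
            raise ConfigError("body_weight must be positive")
        if not 0.0 <= self.distribution_weight < 1.0:
            raise ConfigError("distribution_weight must lie in [0, 1)")
        if self.sampling_interval <= 0 or self.duration <= 0:
            raise ConfigError("sampling_interval and duration must be positive")

    @property
    def elimination_halflife(self) -> float:
        """t_half [min] implied by gfr_true and body_weight."""
        return GFR_CONVERSION_UL / self.gfr_true * self.body_weight / 100.0


def simulate_decay(cfg: DecaySimConfig) -> "DecayCurve":
    """Simulate a (bi-)exponential fluorescence decay curve."""
    from .physio import DecayCurve  # local import to avoid a cycle

    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, cfg.duration + 1e-9, cfg.sampling_interval)
    t_el = cfg.elimination_halflife
    w = cfg.distribution_weight
    f = cfg.amplitude * (
        (1.0 - w) * np.exp2(-t / t_el) + w * np.exp2(-t / cfg.distribution_halflife)
    )
    if cfg.noise_sd > 0:
        f = f + rng.normal(0.0, cfg.noise_sd * cfg.amplitude, t.size)
    return DecayCurve(time=t, fluorescence=f, body_weight=cfg.body_weight)


# --------------------------------------------------------------------------
# ChIP-qPCR Ct values
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChipSimConfig:
    """qPCR Ct triplets with a known true fold enrichment.

    The IgG pulldown is given ``igg_delta_ct`` cycles over diluted input;
    the specific antibody sits ``log2(true_fr)`` cycles below that.
    """

    true_fr: float = 4.0
    ct_input: float = 20.0
    input_dilution_factor: float = 10.0
    igg_delta_ct: float = 8.0
    n_replicates: int = 3
    noise_sd: float = 0.0  # Ct cycles
    locus: str = "CTGF"
    seed: int = 0

    def __post_init__(self):
        if self.true_fr <= 0:
            raise ConfigError("true_fr must be positive")
        if self.input_dilution_factor <= 0:
            raise ConfigError("input_dilution_factor must be positive")
        if self.n_replicates <= 0:
            raise ConfigError("n_replicates must be positive")


def simulate_chip(cfg: ChipSimConfig) -> pd.DataFrame:
    """Simulate a ChIP-qPCR Ct table (specific antibody and IgG rows)."""
    rng = np.random.default_rng(cfg.seed)
    base = cfg.ct_input - math.log2(cfg.input_dilution_factor)
    rows = []
    for rep in range(cfg.n_replicates):
        for antibody, delta in (
            ("specific", cfg.igg_delta_ct - math.log2(cfg.true_fr)),
            ("IgG", cfg.igg_delta_ct),
        ):
            noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
            rows.append(
                {
                    "sample_id": f"{cfg.locus}_{antibody}_{rep}",
                    "antibody": antibody,
                    "locus": cfg.locus,
                    "ct_bound": base + delta + noise,
                    "ct_input": cfg.ct_input,
                    "dilution_factor": cfg.input_dilution_factor,
                }
            )
    return pd.DataFrame(rows)


def with_seed(cfg, seed: int):
    """Return a copy of any generator config with a different seed."""
    return replace(cfg, seed=seed)
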