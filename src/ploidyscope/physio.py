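"""Closed-form physiology computations: transcutaneous GFR and ChIP-qPCR.

Glomerular filtration rate is read out from the plasma half-life of
FITC-sinistrin measured through the skin.  After an initial distribution
phase, the fluorescence decays mono-exponentially; the device formula
converts the elimination half-life and the body weight into a filtration
rate through an empirical constant:

    GFR [ul/min] = 14616.8 [ul] / t_half [min] * bw [g] / 100 [g]

ChIP-qPCR enrichment uses the standard base-2 Ct arithmetic:

    dCt = Ct(bound) - [Ct(input) - log2(input dilution factor)]
    FR  = 2 ** -(dCt(specific antibody) - dCt(normal IgG))
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConfigError, DataError, FitError
from .synthetic import GFR_CONVERSION_UL

__all__ = [
    "DecayCurve",
    "ChipSample",
    "fit_halflife",
    "gfr_from_halflife",
    "normalize_gfr",
    "delta_ct",
    "chip_fold_enrichment",
    "GFR_CONVERSION_UL",
]


@dataclass(frozen=True)
class DecayCurve:
    """A transcutaneous fluorescence time series for one animal."""

    time: np.ndarray  # minutes, monotone increasing
    fluorescence: np.ndarray  # a.u.
    body_weight: float  # g

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "fluorescence", f)
        if t.size != f.size:
            raise DataError("time and fluorescence must have equal length")
        if t.size < 10:
            raise DataError("a decay curve needs >= 10 samples")
        if np.any(np.diff(t) <= 0):
            raise DataError("time must be strictly increasing")
        if self.body_weight <= 0:
            raise DataError("body_weight must be positive")


@dataclass(frozen=True)
class ChipSample:
    """One ChIP-qPCR measurement (bound and input Ct, dilution, antibody)."""

    ct_bound: float
    ct_input: float
    input_dilution_factor: float
    antibody: str = "specific"

    def __post_init__(self):
        if not (math.isfinite(self.ct_bound) and math.isfinite(self.ct_input)):
            raise DataError("Ct values must be finite")
        if self.input_dilution_factor <= 0:
            raise DataError("input_dilution_factor must be positive")


def _loglinear_halflife(t: np.ndarray, f: np.ndarray) -> float:
    # weighting by f approximates least squares on the raw scale and keeps
    # the noisy low-signal tail from dominating the log fit
    slope = np.polyfit(t, np.log(f), 1, w=f)[0]
    if slope >= 0:
        raise FitError("fluorescence does not decay over the fitted segment")
    return math.log(2.0) / abs(slope)


def _biexponential_halflife(t: np.ndarray, f: np.ndarray) -> float:
    def model(t, a, k_fast, b, k_slow):
        return a * np.exp(-k_fast * t) + b * np.exp(-k_slow * t)

    f0 = float(f[0])
    p0 = (0.25 * f0, 0.35, 0.75 * f0, 0.05)
    bounds = ([0.0, 1e-6, 0.0, 1e-6], [np.inf, np.inf, np.inf, np.inf])
    popt, _ = curve_fit(model, t, f, p0=p0, bounds=bounds, maxfev=20000)
    k_slow = min(popt[1], popt[3])
    if k_slow <= 0:
        raise FitError("bi-exponential fit found no decaying elimination phase")
    return math.log(2.0) / k_slow


def fit_halflife(
    curve: DecayCurve,
    discard_initial: float = 10.0,
    method: str = "loglinear",
) -> float:
    """Elimination half-life (minutes) of a fluorescence decay curve.

    ``method="loglinear"`` (default) discards the first ``discard_initial``
    minutes — the fast distribution phase — and fits log-fluorescence
    against time by weighted least squares; ``t_half = ln 2 / |slope|``.
    ``method="biexponential"`` fits the full two-compartment model to the
    whole curve and reports the slow-phase half-life.

    Raises :class:`FitError` if the segment does not decay and
    :class:`DataError` if fewer than 8 positive-fluorescence points remain.
    """
    if method not in ("loglinear", "biexponential"):
        raise ConfigError("method must be 'loglinear' or 'biexponential'")
    keep = (curve.time >= discard_initial) if method == "loglinear" else np.ones(
        curve.time.size, dtype=bool
    )
    keep &= curve.fluorescence > 0
    t, f = curve.time[keep], curve.fluorescence[keep]
    if t.size < 8:
        raise DataError(
            f"need >= 8 positive-fluorescence points after discard, got {t.size}"
        )
    if method == "loglinear":
        return _loglinear_halflife(t, f)
    return _biexponential_halflife(t, f)


def gfr_from_halflife(
    t_half: float,
    body_weight: float,
    conversion_constant: float = GFR_CONVERSION_UL,
) -> float:
    """GFR [ul/min] from the FITC-sinistrin half-life and body weight.

    Applies the device formula ``conversion_constant / t_half * bw / 100``
    with the empirical constant 14616.8 ul.
    """
    if t_half <= 0:
        raise DataError("t_half must be positive")
    if body_weight <= 0:
        raise DataError("body_weight must be positive")
    return conversion_constant / t_half * body_weight / 100.0


def normalize_gfr(
    series: pd.DataFrame,
    sham_group: str = "sham",
    baseline_time: float = 0.0,
) -> pd.DataFrame:
    """Normalise per-animal GFR to baseline and to the sham group.

    ``series`` is long-format with columns ``animal_id, group, time, gfr``.
    Each animal's GFR is divided by its own value at ``baseline_time``,
    then by the mean baseline-ratio of the sham group at the same time
    point.  Returns the frame with ``ratio`` and ``normalized`` columns.

    Raises :class:`DataError` on missing/zero baselines or an empty sham
    group at any time point.
    """
    df = series.copy()
    baseline = df[df["time"] == baseline_time].set_index("animal_id")["gfr"]
    missing = set(df["animal_id"]) - set(baseline.index)
    if missing:
        raise DataError(f"no baseline (time={baseline_time}) for animals {sorted(missing)}")
    if (baseline <= 0).any():
        raise DataError("baseline GFR must be positive for every animal")

    df["ratio"] = df["gfr"] / df["animal_id"].map(baseline)
    sham_mean = (
        df[df["group"] == sham_group].groupby("time")["ratio"].mean()
    )
    if not set(df["time"]).issubset(sham_mean.index):
        raise DataError("sham group must be observed at every time point")
    df["normalized"] = df["ratio"] / df["time"].map(sham_mean)
    return df


def delta_ct(sample: ChipSample) -> float:
    """dCt = Ct(bound) - [Ct(input) - log2(input dilution factor)]."""
    return sample.ct_bound - (sample.ct_input - math.log2(sample.input_dilution_factor))


def chip_fold_enrichment(specific: ChipSample, igg: ChipSample) -> float:
    """Fold enrichment of a specific antibody over the IgG control.

    ``FR = 2 ** -(dCt(specific) - dCt(IgG))``; equal dCt gives FR = 1, and
    each cycle by which the specific pulldown amplifies earlier doubles FR.
    """
    return 2.0 ** (-(delta_ct(specific) - delta_ct(igg)))
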