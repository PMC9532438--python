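"""Per-nucleus DNA-content quantification from PicoGreen intensities.

PicoGreen binds double-stranded DNA stoichiometrically, so the
background-subtracted nuclear intensity is proportional to DNA content.
Ploidy is expressed as fold over a diploid reference: the mean
background-subtracted intensity of healthy diploid tubular nuclei imaged at
identical settings (2C == fold 1.0).  Marker-stratified comparisons (e.g.
YAP1+ vs YAP1- nuclei) use the two-sided Mann-Whitney rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, DataError, TooFewEventsError

__all__ = [
    "MarkerComparison",
    "calibrate_diploid_reference",
    "ploidy_fold",
    "compare_marker_groups",
]


def _net_intensity(records: pd.DataFrame, global_background: float | None) -> np.ndarray:
    intensity = records["intensity"].to_numpy(dtype=float)
    if global_background is not None:
        return intensity - float(global_background)
    return intensity - records["background"].to_numpy(dtype=float)


def calibrate_diploid_reference(
    records: pd.DataFrame,
    min_reference: int = 20,
    trim: float = 0.0,
    global_background: float | None = None,
) -> float:
    """Mean background-subtracted intensity of the diploid reference nuclei.

    Uses rows flagged ``reference_diploid`` (the healthy-biopsy internal
    control).  ``trim`` optionally applies a symmetric trimmed mean
    (fraction per tail) to guard against misflagged >2C nuclei; the default
    is the plain mean.  Raises :class:`TooFewEventsError` below
    ``min_reference`` nuclei and :class:`CalibrationError` if the mean is
    not positive.
    """
    ref = records[records["reference_diploid"].astype(bool)]
    if len(ref) < min_reference:
        raise TooFewEventsError(
            f"need >= {min_reference} diploid reference nuclei, got {len(ref)}"
        )
    net = _net_intensity(ref, global_background)
    mean = float(stats.trim_mean(net, trim)) if trim > 0 else float(net.mean())
    if mean <= 0:
        raise CalibrationError("diploid reference mean is non-positive")
    return mean


def ploidy_fold(
    records: pd.DataFrame,
    reference_mean: float,
    scale: str = "fold",
    saturation_max: float | None = None,
    global_background: float | None = None,
) -> pd.DataFrame:
    """Per-nucleus DNA content as fold over the diploid reference.

    ``fold = (intensity - background) / reference_mean`` (so 2C == 1.0,
    4C == 2.0); ``scale="c_value"`` multiplies by 2 to report C-units.
    Negative folds are clipped to 0 (a warning reports how many).  Nuclei
    at or above ``saturation_max`` are flagged ``saturated`` and their fold
    set to NaN.

    Returns a copy of ``records`` with ``fold`` and ``saturated`` columns.
    """
    if reference_mean <= 0:
        raise DataError("reference_mean must be positive")
    if scale not in ("fold", "c_value"):
        raise DataError("scale must be 'fold' or 'c_value'")

    out = records.copy()
    fold = _net_intensity(records, global_background) / reference_mean
    n_neg = int((fold < 0).sum())
    if n_neg:
        warnings.warn(f"clipped {n_neg} negative fold values to 0", stacklevel=2)
        fold = np.maximum(fold, 0.0)
    if scale == "c_value":
        fold = 2.0 * fold

    saturated = np.zeros(len(records), dtype=bool)
    if saturation_max is not None:
        saturated = records["intensity"].to_numpy(dtype=float) >= saturation_max
        fold = np.where(saturated, np.nan, fold)

    out["fold"] = fold
    out["saturated"] = saturated
    return out


@dataclass(frozen=True)
class MarkerComparison:
    """Two-sided Mann-Whitney comparison of fold values between groups."""

    u_statistic: float  # U of the marker-positive group
    p_value: float
    median_positive: float
    median_negative: float
    n_positive: int
    n_negative: int


def compare_marker_groups(folds: np.ndarray | pd.Series, labels: np.ndarray | pd.Series) -> MarkerComparison:
    """Compare per-nucleus folds between marker-positive and -negative nuclei.

    ``labels`` is boolean (True = marker-positive, e.g. YAP1+).  Saturated
    (NaN) folds are dropped.  Raises :class:`DataError` if either group is
    empty.
    """
    folds = np.asarray(folds, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    keep = np.isfinite(folds)
    folds, labels = folds[keep], labels[keep]
    pos, neg = folds[labels], folds[~labels]
    if pos.size == 0 or neg.size == 0:
        raise DataError("both marker groups must be non-empty")
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided")
    return MarkerComparison(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_positive=float(np.median(pos)),
        median_negative=float(np.median(neg)),
        n_positive=int(pos.size),
        n_negative=int(neg.size),
    )
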