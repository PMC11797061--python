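"""Dot-blot densitometry: standard-curve fitting and dsRNA quantification.

A dilution series of a fully double-stranded standard (bacteriophage Phi6
genomic dsRNA in the reference assay: 500, 250, 125, 63, 31, 16 pg) is
blotted alongside the samples; spot intensities are modelled as linear in
log10(amount), which is a good description of chemiluminescent dot
intensity over a two-fold series.  Unknown amounts are obtained by
inverting the fitted line; intensities outside the standards' range are
censored, never extrapolated.  Saturation of the top standard is flagged by
a warning rather than modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, ParameterError


@dataclass
class StandardSeries:
    """Fitted standard dilution series (intensity vs log10 amount)."""

    amounts: np.ndarray
    intensities: np.ndarray
    intercept: float
    slope: float
    r_squared: float

    @property
    def intensity_range(self) -> tuple[float, float]:
        """Fitted intensities at the smallest and largest standard amounts."""
        lo = self.predict(self.amounts.min())
        hi = self.predict(self.amounts.max())
        return (min(lo, hi), max(lo, hi))

    def predict(self, amount) -> float | np.ndarray:
        return self.intercept + self.slope * np.log10(amount)


def fit_standard_curve(amounts, intensities) -> StandardSeries:
    """Least-squares line of intensity vs log10(amount).

    Requires >= 4 standards with positive amounts; warns on non-monotone
    intensities and on apparent saturation (the top standard having the
    largest, negative residual).
    """
    amounts = np.asarray(amounts, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if amounts.size < 4:
        raise InsufficientDataError("standard curve needs >= 4 points")
    if np.any(amounts <= 0):
        raise ParameterError("standard amounts must be strictly positive")
    if np.any(intensities <= 0):
        raise ParameterError(
            "standard intensities must be positive after background subtraction"
        )
    res = stats.linregress(np.log10(amounts), intensities)
    fitted = res.intercept + res.slope * np.log10(amounts)
    residuals = intensities - fitted

    order = np.argsort(amounts)
    tol = 2.0 * float(np.std(residuals)) + 1e-12
    if np.any(np.diff(intensities[order]) < -tol):
        warnings.warn("standard intensities not monotone in amount", stacklevel=2)
    top = int(np.argmax(amounts))
    if residuals[top] < 0 and np.abs(residuals[top]) == np.abs(residuals).max():
        warnings.warn(
            "top standard below the fitted line by the largest residual: "
            "possible saturation",
            stacklevel=2,
        )
    return StandardSeries(
        amounts=amounts,
        intensities=intensities,
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
    )


def interpolate_amount(
    curve: StandardSeries, intensity: float
) -> tuple[float, str]:
    """Invert the fitted line; returns (amount, flag).

    Flags: ``"ok"`` inside the standards' fitted intensity range, ``"left"``
    below it (value pinned to the smallest standard amount), ``"right"``
    above it (pinned to the largest).
    """
    if not np.isfinite(intensity):
        raise ParameterError("non-finite intensity")
    lo, hi = curve.intensity_range
    tol = 1e-9 * max(1.0, abs(hi))  # keep boundary standards interpolable
    if intensity < lo - tol:
        return float(curve.amounts.min()), "left"
    if intensity > hi + tol:
        return float(curve.amounts.max()), "right"
    amount = 10.0 ** ((intensity - curve.intercept) / curve.slope)
    return float(amount), "ok"


@dataclass
class DsrnaMetrics:
    fractions: dict  # group -> per-sample dsRNA / loaded-total fractions
    group_means: dict  # group -> mean estimated amount (uncensored only)
    n_censored: dict
    fold_difference: float | None  # ratio of group means, largest first


def dsrna_metrics(
    estimates: dict[str, tuple[np.ndarray, list[str]]],
    loaded_totals: dict[str, float],
) -> DsrnaMetrics:
    """Per-sample dsRNA fractions and the fold difference between two groups.

    ``estimates`` maps group -> (amounts, censoring flags) in the units of
    ``loaded_totals``; censored samples are excluded from group means (their
    count is reported).  With all samples of a group censored the fold
    difference is undefined and returned as None.
    """
    fractions, means, n_censored = {}, {}, {}
    for group, (amounts, flags) in estimates.items():
        amounts = np.asarray(amounts, dtype=float)
        keep = np.array([f == "ok" for f in flags])
        n_censored[group] = int((~keep).sum())
        fractions[group] = amounts / loaded_totals[group]
        means[group] = float(amounts[keep].mean()) if keep.any() else np.nan
    fold = None
    vals = [m for m in means.values() if np.isfinite(m)]
    if len(vals) == len(means) == 2:
        hi, lo = max(vals), min(vals)
        if lo > 0:
            fold = float(hi / lo)
    return DsrnaMetrics(
        fractions=fractions,
        group_means=means,
        n_censored=n_censored,
        fold_difference=fold,
    )
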