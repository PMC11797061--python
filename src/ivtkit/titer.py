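"""Spearman-Karber endpoint titration for CCID50 estimation.

An endpoint dilution assay inoculates replicate wells with a serial dilution
of a virus stock and scores each well infected / not infected.  The fifty
percent cell culture infective dose (CCID50) titer is estimated from the
infected proportions with the Spearman-Karber formula and expressed as a
decimal logarithm.

Convention used here (several equivalent statements exist): with dilution
exponents x_i = log10(reciprocal dilution), equally spaced with step d and
anchored at the lowest exponent x_0,

    log10 CCID50 = x_0 + d * (sum_i p_i - 0.5)

where p_i is the infected proportion at dilution i and the sum runs over all
dilutions.  The formula requires the 50% endpoint to be bracketed (all wells
infected at the lowest exponent, none at the highest); otherwise the titer
is censored beyond the series and reported as a bound, never a number.
Per-volume normalization (e.g. per ml of inoculum) is a reporting multiplier
applied by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError


@dataclass
class DilutionAssay:
    """Infection matrix of an endpoint dilution series.

    ``exponents`` must be strictly increasing and equally spaced.
    """

    exponents: np.ndarray
    wells_total: np.ndarray
    wells_infected: np.ndarray

    def __post_init__(self) -> None:
        self.exponents = np.asarray(self.exponents, dtype=float)
        self.wells_total = np.asarray(self.wells_total, dtype=np.int64)
        self.wells_infected = np.asarray(self.wells_infected, dtype=np.int64)
        if not (
            self.exponents.shape
            == self.wells_total.shape
            == self.wells_infected.shape
        ):
            raise ParameterError("assay columns differ in length")
        if self.exponents.size < 2:
            raise ParameterError("need at least two dilutions")
        steps = np.diff(self.exponents)
        if np.any(steps <= 0):
            raise ParameterError("dilution exponents must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ParameterError("dilution exponents must be equally spaced")
        if np.any(self.wells_total <= 0):
            raise ParameterError("wells_total must be positive")
        if np.any(self.wells_infected < 0) or np.any(
            self.wells_infected > self.wells_total
        ):
            raise ParameterError("wells_infected outside [0, wells_total]")

    @property
    def step(self) -> float:
        return float(self.exponents[1] - self.exponents[0])

    @property
    def proportions(self) -> np.ndarray:
        return self.wells_infected / self.wells_total


@dataclass
class TiterResult:
    """log10 CCID50 estimate, or a censored bound when unbracketed.

    ``censored`` is ``None`` for a proper estimate, ``">"`` when every
    dilution still infects (titer beyond the highest exponent) and ``"<"``
    when even the lowest dilution fails to infect all wells.
    """

    log10_titer: float
    censored: str | None = None

    @property
    def is_censored(self) -> bool:
        return self.censored is not None


def spearman_karber(assay: DilutionAssay) -> TiterResult:
    """Spearman-Karber log10 CCID50 estimate for one dilution series."""
    p = assay.proportions
    if p[-1] > 0:
        return TiterResult(float(assay.exponents[-1]), censored=">")
    if p[0] < 1:
        return TiterResult(float(assay.exponents[0]), censored="<")
    estimate = assay.exponents[0] + assay.step * (p.sum() - 0.5)
    return TiterResult(float(estimate))
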