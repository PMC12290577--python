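"""Gamma-variate capillary transit-time distributions.

The microvascular model underlying the whole pipeline: capillary transit
times are distributed as a gamma variate h(t) with shape ``alpha`` and scale
``beta`` (seconds).  The residue function used by the DSC deconvolution is
the survival function of h, and the summary statistics every downstream
module consumes are closed forms of (alpha, beta):

* MTT  = alpha * beta          (mean transit time, s)
* CTH  = sqrt(alpha) * beta    (transit-time standard deviation, s)
* RTH  = CTH / MTT = 1/sqrt(alpha)   (relative heterogeneity, unitless)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special


@dataclass(frozen=True)
class TransitTimeDistribution:
    """Gamma-variate transit-time distribution h(t).

    Parameters
    ----------
    alpha:
        Shape parameter (dimensionless), strictly positive.
    beta:
        Scale parameter (seconds), strictly positive.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"shape alpha must be finite and > 0, got {self.alpha}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"scale beta must be finite and > 0, got {self.beta}")

    @classmethod
    def from_moments(cls, mtt: float, cth: float) -> "TransitTimeDistribution":
        """Build from mean transit time and transit-time SD (both seconds)."""
        if not (mtt > 0 and cth > 0):
            raise ValueError("mtt and cth must be > 0 to define a gamma variate")
        alpha = (mtt / cth) ** 2
        beta = cth**2 / mtt
        return cls(alpha=alpha, beta=beta)

    @property
    def mean(self) -> float:
        return self.alpha * self.beta

    @property
    def std(self) -> float:
        return float(np.sqrt(self.alpha)) * self.beta


@dataclass(frozen=True)
class TransitSummary:
    """Hemodynamic summary of a transit-time distribution."""

    mtt: float  # seconds
    cth: float  # seconds
    rth: float  # dimensionless, cth/mtt


def transit_density(t, d: TransitTimeDistribution):
    """Gamma pdf h(t) = t^(a-1) exp(-t/b) / (Gamma(a) b^a), for t >= 0.

    Accepts scalars or arrays; negative times raise.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("transit times must be nonnegative")
    a, b = d.alpha, d.beta
    with np.errstate(divide="ignore"):
        logpdf = special.xlogy(a - 1.0, t / b) - t / b - special.gammaln(a) - np.log(b)
    out = np.exp(logpdf)
    # xlogy(a-1, 0) = 0 for a=1 -> pdf(0) = 1/b; for a<1 the pdf diverges at 0
    if out.ndim == 0:
        return float(out)
    return out


def residue_function(t, d: TransitTimeDistribution):
    """Residue function R(t) = 1 - CDF_gamma(t; alpha, beta).

    Fraction of tracer still inside the vasculature t seconds after an
    idealized instantaneous injection.  R(0) = 1, nonincreasing, -> 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("transit times must be nonnegative")
    out = special.gammaincc(d.alpha, t / d.beta)
    if out.ndim == 0:
        return float(out)
    return out


def transit_summary(d: TransitTimeDistribution) -> TransitSummary:
    """Closed-form MTT, CTH and RTH of a gamma transit-time distribution."""
    sqrt_a = float(np.sqrt(d.alpha))
    return TransitSummary(mtt=d.alpha * d.beta, cth=sqrt_a * d.beta, rth=1.0 / sqrt_a)


def quantile(d: TransitTimeDistribution, q: float) -> float:
    """Inverse CDF of the transit-time distribution (seconds)."""
    if not 0.0 <= q < 1.0:
        raise ValueError("quantile level must be in [0, 1)")
    return float(special.gammaincinv(d.alpha, q) * d.beta)
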