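"""Labelling statistics and culture-level rate computations.

* SFL (summed fractional labelling): the average number of 13C atoms in a
  fragment, SFL = sum(i * M_i) / sum(M_i); for a normalized MID this is
  simply sum(i * M_i), ranging from 0 to the backbone carbon count C.

* R-value: for mixotrophic growth on [1,2-13C]glycerol (n = 2 labelled of
  m = 3 carbons, 99 atom% purity) plus CO2 at 1% natural 13C abundance, the
  two-source mixing model

      (0.99 n V_gly + 0.01 V_co2) / (m V_gly + V_co2) = SFL / C

  inverts to R = V_gly / V_co2 = (f - 0.01) / (0.99 n - m f) with
  f = SFL / C.  R is defined only for 0.01 < f < 0.99 n / m; outside this
  window the fragment's labelling is inconsistent with the two-source model.

* Specific growth rate mu from the least-squares slope of ln(OD) vs time,
  doubling time ln(2)/mu, and substrate uptake rate from the regression of
  consumed substrate on the time integral of OD (units g L^-1 OD^-1 h^-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

__all__ = [
    "SFLValue",
    "RValue",
    "GrowthSeries",
    "sfl",
    "r_value_from_sfl",
    "r_value_from_mid",
    "growth_rate",
    "uptake_rate",
    "RValueDomainError",
]


class RValueDomainError(ValueError):
    """Fractional labelling outside the domain of the two-source model."""


@dataclass(frozen=True)
class SFLValue:
    value: float
    n_carbons: int

    def __float__(self):
        return self.value


@dataclass(frozen=True)
class RValue:
    """Ratio of carbon flux from labelled glycerol to flux from CO2."""

    value: float
    n: int = 2            # tracer-labelled carbons in glycerol
    m: int = 3            # total glycerol carbons
    purity: float = 0.99
    co2_abundance: float = 0.01

    def __float__(self):
        return self.value


def sfl(mid, n_carbons: int | None = None) -> SFLValue:
    """Summed fractional labelling of a MID.

    Implemented as the ratio sum(i*M_i)/sum(M_i) so an explicit
    normalization step is applied; an all-zero or negative input raises.
    """
    arr = np.asarray(mid, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("MID must be a 1-D vector")
    if np.any(arr < 0):
        raise ValueError("MID fractions must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("cannot compute SFL of an all-zero MID")
    value = float(np.arange(arr.size) @ arr / total)
    return SFLValue(value, n_carbons if n_carbons is not None else arr.size - 1)


def r_value_from_sfl(sfl_value: float, n_carbons: int, n: int = 2, m: int = 3,
                     purity: float = 0.99,
                     co2_abundance: float = 0.01) -> RValue:
    """Invert the two-source mixing model at a given SFL."""
    if n_carbons <= 0:
        raise ValueError("n_carbons must be positive")
    f = float(sfl_value) / n_carbons
    upper = purity * n / m
    if not co2_abundance < f < upper:
        raise RValueDomainError(
            f"fractional labelling {f:.4f} outside ({co2_abundance}, "
            f"{upper:.4f}): inconsistent with the glycerol+CO2 model")
    value = (f - co2_abundance) / (purity * n - m * f)
    return RValue(value, n=n, m=m, purity=purity, co2_abundance=co2_abundance)


def r_value_from_mid(mid, n: int = 2, m: int = 3, purity: float = 0.99,
                     co2_abundance: float = 0.01) -> RValue:
    """R-value of a fragment MID (C = len(mid) - 1 backbone carbons)."""
    s = sfl(mid)
    return r_value_from_sfl(s.value, s.n_carbons, n=n, m=m, purity=purity,
                            co2_abundance=co2_abundance)


@dataclass
class GrowthSeries:
    """OD600 (and optionally substrate concentration, g/L) vs time (h)."""

    times: np.ndarray
    od600: np.ndarray
    substrate_conc: np.ndarray | None = None
    condition: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.substrate_conc is not None:
            self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od600 <= 0):
            raise ValueError("OD600 must be positive")


def growth_rate(series: GrowthSeries, od_window=None):
    """Specific growth rate mu (1/h) and doubling time (h).

    mu is the least-squares slope of ln(OD) vs time over the exponential
    phase; ``od_window=(lo, hi)`` optionally restricts the points used.
    """
    t, od = series.times, series.od600
    if od_window is not None:
        lo, hi = od_window
        keep = (od >= lo) & (od <= hi)
        t, od = t[keep], od[keep]
    if t.size < 3:
        raise ValueError("need at least 3 points in the exponential phase")
    fit = stats.linregress(t, np.log(od))
    mu = float(fit.slope)
    if mu <= 0:
        raise ValueError(f"non-positive growth rate {mu:.4g}")
    return mu, float(np.log(2) / mu)


def uptake_rate(series: GrowthSeries) -> float:
    """Biomass-specific substrate uptake rate, g L^-1 OD^-1 h^-1.

    Under exponential growth with a constant specific uptake rate q, the
    substrate obeys dc/dt = -q OD(t), so c(t) = c0 - q * int OD dt.  q is
    the (sign-flipped) regression slope of concentration on the trapezoidal
    integral of OD.  A net increase of substrate triggers a warning and a
    negative return value.
    """
    if series.substrate_conc is None:
        raise ValueError("series has no substrate concentrations")
    t, od, c = series.times, series.od600, series.substrate_conc
    if t.size < 2:
        raise ValueError("need at least 2 concentration points")
    cum = integrate.cumulative_trapezoid(od, t, initial=0.0)
    fit = stats.linregress(cum, c)
    rate = -float(fit.slope)
    if rate < 0:
        warnings.warn("substrate concentration increases over time: "
                      "net production, returning negative uptake rate")
    return rate
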