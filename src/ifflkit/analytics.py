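"""Closed-form predictions for the base IFFL under square pulse trains.

Because the intermediate x is a driven first-order species decoupled from
the reporter, its per-cycle extrema obey an exact linear recursion::

    x_basal,i = x_peak,i-1 * exp(-(T - D))
    x_peak,i  = beta - (beta - x_basal,i) * exp(-D)

starting from x_peak,0 = 0.  Counting fails at the first pulse n_c whose
peak exceeds the half-activation threshold x = 1 (the counting capacity);
the peak sequence is geometric with ratio exp(-T) and limit
beta*(1 - exp(-D))/(1 - exp(-T)), so indefinite counting (n_c = infinity)
holds exactly when (1 - exp(-D))/(1 - exp(-T)) < 1/beta.  As T -> infinity
the border reduces to 1 = beta*(1 - exp(-D)).

While every peak stays sub-threshold the reporter sees no induced
degradation and its endpoint level after k pulses has the closed form::

    r(tauE) = (beta/gamma_o) * (1 - exp(-gamma_o*D))
              * sum_{i=0}^{k-1} exp(-gamma_o*(tauE - tau0 - (i*T + D)))

with gamma_o -> 0 limit k*beta*D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CapacityResult",
    "peak_basal_sequence",
    "counting_capacity",
    "border_beta",
    "border_duration",
    "indefinite_counting",
    "endpoint_closed_form",
    "relative_duration_border",
    "NoBorderError",
]


class NoBorderError(ValueError):
    """The counting border does not exist (threshold unreachable)."""


@dataclass(frozen=True)
class CapacityResult:
    """Counting capacity with the peak/basal sequences that produced it.

    nc is the index (1-based) of the first peak exceeding the threshold,
    or ``math.inf`` when the peak sequence converges below it.
    """

    nc: float  # positive integer or math.inf
    peaks: tuple[float, ...]
    basals: tuple[float, ...]

    @property
    def is_indefinite(self) -> bool:
        return math.isinf(self.nc)


def _check_train(T: float, D: float) -> None:
    if not 0 < D < T:
        raise ValueError(f"need 0 < D < T, got D={D}, T={T}")


def peak_basal_sequence(beta: float, T: float, D: float, k: int,
                        ) -> tuple[list[float], list[float]]:
    """Iterate the exact per-cycle recursion for k pulses.

    Returns (peaks, basals), each of length k; peak_1 = beta*(1 - e^-D),
    basal_1 = 0.
    """
    _check_train(T, D)
    if k < 0:
        raise ValueError(f"k must be nonnegative, got {k}")
    decay_off = math.exp(-(T - D))
    decay_on = math.exp(-D)
    peaks: list[float] = []
    basals: list[float] = []
    peak = 0.0
    for _ in range(k):
        basal = peak * decay_off
        peak = beta - (beta - basal) * decay_on
        basals.append(basal)
        peaks.append(peak)
    return peaks, basals


def _peak_limit(beta: float, T: float, D: float) -> float:
    """Fixed point of the peak recursion (geometric ratio e^-T)."""
    return beta * (1.0 - math.exp(-D)) / (1.0 - math.exp(-T))


def counting_capacity(beta: float, T: float, D: float,
                      max_pulses: int = 1000) -> CapacityResult:
    """First pulse index whose intermediate peak exceeds the threshold.

    The infinity decision is exact: peaks increase geometrically toward
    ``beta*(1-e^-D)/(1-e^-T)``, so nc is infinite iff that limit does not
    exceed 1 (equality never crosses the strict threshold).  Otherwise nc
    is found by iterating the recursion (up to ``max_pulses``, then from
    the closed form of the geometric sequence).
    """
    _check_train(T, D)
    limit = _peak_limit(beta, T, D)
    stored = min(max_pulses, 50)
    peaks, basals = peak_basal_sequence(beta, T, D, stored)
    if limit <= 1.0:
        return CapacityResult(nc=math.inf, peaks=tuple(peaks),
                              basals=tuple(basals))
    for i, p in enumerate(peaks, start=1):
        if p > 1.0:
            return CapacityResult(nc=i, peaks=tuple(peaks[:i]),
                                  basals=tuple(basals[:i]))
    # peak_i = limit*(1 - e^{-iT}) > 1  <=>  i > -ln(1 - 1/limit)/T
    nc = math.floor(-math.log(1.0 - 1.0 / limit) / T) + 1
    return CapacityResult(nc=nc, peaks=tuple(peaks), basals=tuple(basals))


def border_beta(D: float) -> float:
    """Synthesis rate at the counting border for duration D: 1/(1 - e^-D).

    Below this beta a single pulse of duration D cannot push the
    intermediate to its threshold.
    """
    if D <= 0:
        raise ValueError(f"D must be positive, got {D}")
    return 1.0 / (1.0 - math.exp(-D))


def border_duration(beta: float) -> float:
    """Pulse duration at the counting border for synthesis rate beta.

    Inverse of :func:`border_beta`: D* = ln(beta/(beta - 1)).  For
    beta <= 1 the threshold is unreachable at any duration and no border
    exists.
    """
    if beta <= 1.0:
        raise NoBorderError(
            f"no counting border for beta={beta} <= 1: the intermediate "
            "can never reach its threshold")
    return math.log(beta / (beta - 1.0))


def indefinite_counting(beta: float, T: float, D: float) -> bool:
    """Whether the peak sequence stays below threshold forever.

    Evaluates (1 - e^-D)/(1 - e^-T) < 1/beta; for beta <= 1 this always
    holds (treating beta = 0 as trivially counting).  As T -> infinity the
    condition reduces to beta*(1 - e^-D) < 1.
    """
    _check_train(T, D)
    if beta <= 0:
        return True
    return (1.0 - math.exp(-D)) / (1.0 - math.exp(-T)) < 1.0 / beta


def endpoint_closed_form(beta: float, gamma_o: float, D: float, T: float,
                         k: int, tau0: float = 1.0,
                         tauE: float | None = None) -> float:
    """Closed-form endpoint r(tauE) after k sub-threshold pulses.

    Valid while the intermediate never triggers induced degradation
    (the 1 > beta*(1 - e^-D) regime).  At gamma_o = 0 the sum collapses to
    the proportional law k*beta*D.
    """
    if k < 0:
        raise ValueError(f"k must be nonnegative, got {k}")
    if gamma_o < 0:
        raise ValueError(f"gamma_o must be nonnegative, got {gamma_o}")
    if k == 0:
        return 0.0
    if tauE is None:
        tauE = tau0 + k * T
    if tauE <= (k - 1) * T + D + tau0:
        raise ValueError(
            f"tauE={tauE} must follow the end of the last pulse "
            f"({(k - 1) * T + D + tau0})")
    if gamma_o == 0.0:
        return k * beta * D
    i = np.arange(k)
    tail = np.exp(-gamma_o * (tauE - tau0 - (i * T + D)))
    return float(beta / gamma_o * (1.0 - math.exp(-gamma_o * D)) * tail.sum())


def relative_duration_border(beta: float, T) -> np.ndarray | float:
    """Relative duration D/T at the counting border for each period T.

    Solves (1 - e^-D) = (1 - e^-T)/beta for D by bracketed root finding
    (the left side is strictly increasing in D) and returns D/T.  As
    T -> infinity, D converges to ln(beta/(beta-1)) so D/T -> 0.
    """
    if beta <= 1.0:
        raise NoBorderError(
            f"no counting border for beta={beta} <= 1")
    Ts = np.atleast_1d(np.asarray(T, dtype=float))
    out = np.empty_like(Ts)
    for j, Tj in enumerate(Ts):
        if Tj <= 0:
            raise ValueError(f"T must be positive, got {Tj}")
        target = (1.0 - math.exp(-Tj)) / beta
        # D* < T always since target < (1 - e^-T)
        f = lambda d: (1.0 - math.exp(-d)) - target
        D = brentq(f, 1e-300, Tj, xtol=1e-10, rtol=8.9e-16)
        out[j] = D / Tj
    if np.ndim(T) == 0:
        return float(out[0])
    return out
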