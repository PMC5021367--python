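"""Right-hand sides of the IFFL models and the dimensional/dimensionless map.

The core motif: an input S drives production of an intermediate X and a
reporter R; X induces degradation of R through an ultrasensitive
(high-Hill-coefficient) threshold response.  In dimensionless form::

    dr/dtau = beta*Phi(tau) - (gamma_R * x^n/(x^n + 1) + gamma_o) * r
    dx/dtau = beta*Phi(tau) - x

where concentrations are measured in units of the half-activation threshold
K_x and time in units of 1/d_x (the intermediate's turnover time).  The
dimensional model and the supplementary architecture variants (positive
feedback, delayed inhibition or activation arm, repression) are defined here
as plain derivative functions suitable for any ODE integrator.

Variant state orderings (inputs first, reporter last):

* ``positive_feedback`` and ``repression``: ``(x, r)``
* ``delay_inhibition``: ``(x1, x, r)`` — x1 is the input-driven first stage
* ``delay_activation``: ``(x, r1, r)`` — r1 is the intermediate reporter
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import expit

from .signals import PulseTrain

__all__ = [
    "IFFLParams",
    "DimensionalParams",
    "VariantParams",
    "hill_activation",
    "base_derivatives",
    "dimensional_derivatives",
    "variant_derivatives",
    "nondimensionalize",
    "VARIANT_STATE_NAMES",
]


@dataclass(frozen=True)
class IFFLParams:
    """Dimensionless kinetic parameters of the base IFFL.

    beta     maximal synthesis rate of X and R (in units of K_x * d_x);
             the system can only discriminate signals when beta > 1.
    gamma_R  maximal induced degradation rate of R by X (units of d_x).
    gamma_o  basal degradation rate constant of R (units of d_x).
    n        Hill coefficient of the induced-degradation threshold;
             effectively switch-like at the default 110.
    """

    beta: float = 1.2
    gamma_R: float = 10.0
    gamma_o: float = 0.0
    n: float = 110.0

    def __post_init__(self) -> None:
        for name in ("beta", "gamma_R", "gamma_o", "n"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.beta < 0:
            raise ValueError(f"beta must be nonnegative, got {self.beta}")
        if self.gamma_R < 0 or self.gamma_o < 0:
            raise ValueError("degradation rates must be nonnegative")
        if self.n < 1:
            raise ValueError(f"Hill coefficient n must be >= 1, got {self.n}")

    def to_dict(self) -> dict:
        return {"beta": self.beta, "gamma_R": self.gamma_R,
                "gamma_o": self.gamma_o, "n": self.n}

    @classmethod
    def from_dict(cls, mapping: dict) -> "IFFLParams":
        return cls(**mapping)


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional parameters of the full (molecular-number) model.

    k1, k2   production rate constants of R and X.
    dx       endogenous degradation rate of X (> 0; sets the time scale).
    dR       maximal induced degradation rate of R.
    dRo      endogenous degradation rate of R.
    Kx       half-activation threshold of X (> 0; sets the X scale).
    n        Hill coefficient.
    """

    k1: float = 5.0
    k2: float = 5.0
    dx: float = 1.0
    dR: float = 10.0
    dRo: float = 0.0
    Kx: float = 4.0
    n: float = 110.0

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise ValueError(f"dx must be positive, got {self.dx}")
        if self.Kx <= 0:
            raise ValueError(f"Kx must be positive, got {self.Kx}")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("production rates k1, k2 must be positive")
        if self.dR < 0 or self.dRo < 0:
            raise ValueError("degradation rates must be nonnegative")
        if self.n < 1:
            raise ValueError(f"Hill coefficient n must be >= 1, got {self.n}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "DimensionalParams":
        return cls(**mapping)


_VARIANTS = ("positive_feedback", "delay_inhibition", "delay_activation",
             "repression")

VARIANT_STATE_NAMES: dict[str, tuple[str, ...]] = {
    "positive_feedback": ("x", "r"),
    "repression": ("x", "r"),
    "delay_inhibition": ("x1", "x", "r"),
    "delay_activation": ("x", "r1", "r"),
}


@dataclass(frozen=True)
class VariantParams:
    """Parameters of an alternative IFFL architecture.

    variant selects the architecture; only the fields that architecture
    uses may be set:

    * ``positive_feedback``: the ultrasensitive threshold moves into the
      production of X (strength ``alpha``); degradation of R is bilinear in
      X and R.  Uses ``beta``, ``gamma_R``, ``gamma_o``, ``n``, ``alpha``.
    * ``delay_inhibition``: a first-order stage x1 (synthesis ``beta_p``,
      decay ``delta``) is inserted between the input and X (synthesis
      ``beta_pp``).
    * ``delay_activation``: a first-order intermediate reporter r1
      (synthesis ``beta_p``, decay ``gamma_R1``) is inserted between the
      input and R (synthesis ``beta_pp``).
    * ``repression``: X represses production of R through the threshold
      instead of inducing its degradation.  Uses ``beta``, ``gamma_o``, ``n``.
    """

    variant: str
    beta: float | None = None
    beta_p: float | None = None
    beta_pp: float | None = None
    alpha: float | None = None
    delta: float | None = None
    gamma_R: float | None = None
    gamma_R1: float | None = None
    gamma_o: float = 0.0
    n: float = 110.0

    _REQUIRED = {
        "positive_feedback": ("beta", "gamma_R", "alpha"),
        "delay_inhibition": ("beta_p", "beta_pp", "delta", "gamma_R"),
        "delay_activation": ("beta_p", "beta_pp", "gamma_R", "gamma_R1"),
        "repression": ("beta",),
    }
    _FORBIDDEN = {
        "positive_feedback": ("beta_p", "beta_pp", "delta", "gamma_R1"),
        "delay_inhibition": ("beta", "alpha", "gamma_R1"),
        "delay_activation": ("beta", "alpha", "delta"),
        "repression": ("beta_p", "beta_pp", "alpha", "delta", "gamma_R",
                       "gamma_R1"),
    }

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(
                f"variant must be one of {_VARIANTS}, got {self.variant!r}")
        for name in self._REQUIRED[self.variant]:
            v = getattr(self, name)
            if v is None:
                raise ValueError(
                    f"variant {self.variant!r} requires parameter {name!r}")
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name in self._FORBIDDEN[self.variant]:
            if getattr(self, name) is not None:
                raise ValueError(
                    f"parameter {name!r} does not apply to variant "
                    f"{self.variant!r}")
        if self.gamma_o < 0:
            raise ValueError("gamma_o must be nonnegative")
        if self.n < 1:
            raise ValueError(f"Hill coefficient n must be >= 1, got {self.n}")

    @property
    def state_names(self) -> tuple[str, ...]:
        return VARIANT_STATE_NAMES[self.variant]

    def to_dict(self) -> dict:
        d = {"variant": self.variant, "gamma_o": self.gamma_o, "n": self.n}
        for name in self._REQUIRED[self.variant]:
            d[name] = getattr(self, name)
        return d

    @classmethod
    def from_dict(cls, mapping: dict) -> "VariantParams":
        return cls(**mapping)


def hill_activation(x, n: float):
    """Ultrasensitive activation fraction ``x^n / (x^n + 1)``.

    Evaluated in log space as ``logistic(n * ln x)`` so that steep Hill
    coefficients (n ~ 100) never overflow: x^n exceeds double precision
    already for x > 1.3 at n = 110.  Accepts scalars or arrays; x must be
    nonnegative.
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0):
        raise ValueError("hill_activation requires x >= 0")
    out = np.zeros_like(xa)
    pos = xa > 0
    with np.errstate(divide="ignore"):
        out[pos] = expit(n * np.log(xa[pos]))
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def base_derivatives(state, tau: float, params: IFFLParams, input_level: float):
    """(dx/dtau, dr/dtau) of the base dimensionless IFFL.

    ``input_level`` is the already amplitude-scaled signal Phi(tau).
    """
    x, r = state
    drive = params.beta * input_level
    dx = drive - x
    # solver trial steps may dip infinitesimally below zero
    dr = drive - (params.gamma_R * hill_activation(max(x, 0.0), params.n)
                  + params.gamma_o) * r
    return dx, dr


def dimensional_derivatives(state, t: float, params: DimensionalParams,
                            input_level: float):
    """(d[X]/dt, d[R]/dt) of the dimensional model on molecular numbers."""
    X, R = state
    dX = params.k2 * input_level - params.dx * X
    dR = (params.k1 * input_level
          - params.dR * hill_activation(max(X, 0.0) / params.Kx, params.n) * R
          - params.dRo * R)
    return dX, dR


def variant_derivatives(state, tau: float, params: VariantParams,
                        input_level: float):
    """Derivatives of the selected architecture variant.

    State ordering per variant is given by ``VARIANT_STATE_NAMES`` (inputs
    first, reporter last).
    """
    v = params.variant
    expected = len(VARIANT_STATE_NAMES[v])
    if len(state) != expected:
        raise ValueError(
            f"variant {v!r} expects a state of dimension {expected}, "
            f"got {len(state)}")
    n = params.n
    if v == "positive_feedback":
        # threshold response moved into X production; degradation of R is
        # bilinear in X and R
        x, r = state
        dx = (params.beta * input_level
              + params.alpha * hill_activation(max(x, 0.0), n) - x)
        dr = params.beta * input_level - (params.gamma_R * x + params.gamma_o) * r
        return dx, dr
    if v == "repression":
        # X gates production of R through the threshold; no induced degradation
        x, r = state
        dx = params.beta * input_level - x
        dr = (params.beta * input_level * (1.0 - hill_activation(max(x, 0.0), n))
              - params.gamma_o * r)
        return dx, dr
    if v == "delay_inhibition":
        # input -> x1 -> X; X degrades R through the threshold
        x1, x, r = state
        dx1 = params.beta_p * input_level - params.delta * x1
        dx = params.beta_pp * x1 - x
        dr = (params.beta_pp * input_level
              - (params.gamma_R * hill_activation(max(x, 0.0), n)
                 + params.gamma_o) * r)
        return dx1, dx, dr
    # delay_activation: input -> r1 -> R; X acts directly on R
    x, r1, r = state
    dx = params.beta_pp * input_level - x
    dr1 = params.beta_p * input_level - params.gamma_R1 * r1
    dr = (params.beta_pp * r1
          - (params.gamma_R * hill_activation(max(x, 0.0), n)
                 + params.gamma_o) * r)
    return dx, dr1, dr


def nondimensionalize(params: DimensionalParams,
                      train: PulseTrain | None = None,
                      t0: float | None = None,
                      ) -> tuple[IFFLParams, PulseTrain | None, float]:
    """Map the dimensional model onto the dimensionless one.

    Concentrations scale by the threshold (x = [X]/Kx,
    r = [R]*k2/(k1*Kx)) and time by the intermediate's turnover
    (tau = t*dx), giving::

        beta = k2/(Kx*dx),  gamma_R = dR/dx,  gamma_o = dRo/dx

    Parameters
    ----------
    params : DimensionalParams
    train : PulseTrain, optional
        A train in *dimensional* time; its T, D, tau0 are rescaled by dx.
    t0 : float, optional
        Overrides the train's start time (dimensional) if given.

    Returns
    -------
    (IFFLParams, PulseTrain or None, float)
        The dimensionless parameters, the rescaled train, and the reporter
        scale factor ``k2/(k1*Kx)`` mapping [R] to r.
    """
    p = IFFLParams(
        beta=params.k2 / (params.Kx * params.dx),
        gamma_R=params.dR / params.dx,
        gamma_o=params.dRo / params.dx,
        n=params.n,
    )
    reporter_scale = params.k2 / (params.k1 * params.Kx)
    scaled = None
    if train is not None:
        tau0 = (t0 if t0 is not None else train.tau0) * params.dx
        scaled = PulseTrain(
            k=train.k,
            T=train.T * params.dx,
            D=train.D * params.dx,
            tau0=tau0,
            amplitude=train.amplitude,
            waveform=train.waveform,
        )
    return p, scaled, reporter_scale
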