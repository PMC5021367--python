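"""Calibration curves: endpoint reporter level versus number of pulses.

A network "counts" when the reporter read at a fixed time tauE grows
linearly with the number of input pulses k.  An ordinary least-squares line
of r(tauE) on k quantifies this: the slope measures the strength of the
response and the coefficient of determination R^2 its quality.  R^2 >= 0.99
is the cut-off for high-quality counting; a flat (no-response) calibration
is reported as R^2 = 0, absolute failure; anything in between is
low-quality counting (the reporter saturates with pulse number).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from . import engine
from .engine import StochasticConfig, Trajectory
from .models import DimensionalParams, IFFLParams, VariantParams
from .signals import PulseTrain

__all__ = [
    "CalibrationCurve",
    "calibration_curve",
    "linear_fit",
    "classify_counting",
    "HIGH_QUALITY_R2",
]

#: R^2 cut-off for high-quality counting
HIGH_QUALITY_R2 = 0.99
#: variance floor of the degenerate (flat-response) rule, relative to the
#: squared mean readout
EPS_VAR = 1e-6
#: slope floor, relative to the natural per-pulse increment beta*D
EPS_SLOPE_REL = 1e-3


@dataclass(frozen=True)
class CalibrationCurve:
    """Endpoint readouts r(tauE) per pulse count with the fitted line."""

    ks: tuple[int, ...]
    readouts: tuple[float, ...]
    tauE: float
    slope: float
    intercept: float
    r_squared: float
    counting_class: str
    params: object = None
    train_template: PulseTrain | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"k": self.ks, "readout": self.readouts})

    def summary(self) -> dict:
        return {
            "tauE": self.tauE,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "counting_class": self.counting_class,
        }


def classify_counting(r_squared: float, slope: float | None = None) -> str:
    """high_quality (R^2 >= 0.99), failure (R^2 = 0) or low_quality."""
    if not 0.0 <= r_squared <= 1.0:
        raise ValueError(f"r_squared must lie in [0, 1], got {r_squared}")
    if r_squared >= HIGH_QUALITY_R2:
        return "high_quality"
    if r_squared == 0.0:
        return "failure"
    return "low_quality"


def linear_fit(ks: Sequence[int], readouts: Sequence[float],
               slope_scale: float | None = None,
               ) -> tuple[float, float, float]:
    """OLS line of readouts on ks: (slope, intercept, r_squared).

    A flat response would leave raw OLS with a 0/0 coefficient of
    determination; the degenerate rule makes failure well-defined: if the
    readouts' total sum of squares is below ``EPS_VAR * mean^2``, or the
    fitted |slope| is below ``EPS_SLOPE_REL * slope_scale`` (a scale-aware
    floor, e.g. beta*D, the ideal per-pulse increment), R^2 is reported
    as 0.
    """
    ks = np.asarray(ks, dtype=float)
    y = np.asarray(readouts, dtype=float)
    if len(ks) < 3 or len(y) != len(ks):
        raise ValueError("need at least 3 (k, readout) pairs of equal length")

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    floor = EPS_VAR * y.mean() ** 2
    if ss_tot <= floor:
        # flat response: slope ~ 0 by construction
        res = stats.linregress(ks, y)
        return float(res.slope), float(res.intercept), 0.0
    res = stats.linregress(ks, y)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue**2)
    if slope_scale is not None and abs(slope) < EPS_SLOPE_REL * slope_scale:
        return slope, intercept, 0.0
    return slope, intercept, r2


def default_readout_time(train_template: PulseTrain, ks: Sequence[int]) -> float:
    """Shared readout time tau0 + max(k)*T used for every k in a curve."""
    return train_template.tau0 + max(ks) * train_template.T


def calibration_curve(
    params,
    train_template: PulseTrain,
    ks: Sequence[int] | None = None,
    tauE: float | None = None,
    *,
    stochastic: StochasticConfig | None = None,
    rtol: float = engine.DEFAULT_RTOL,
    atol: float = engine.DEFAULT_ATOL,
) -> CalibrationCurve:
    """Simulate over k pulses for each k and fit the calibration line.

    All simulations share the template's T, D, tau0, waveform and amplitude;
    only the pulse count varies.  Every readout is taken at the same fixed
    tauE (default ``tau0 + max(ks)*T``), which must fall after the last
    pulse of the largest train.

    When ``stochastic`` is given, each k is simulated with the
    Euler–Maruyama molecular-number integrator (replicates averaged,
    sub-seeds drawn from the config seed) and ``params`` is ignored in
    favour of ``stochastic.params``.
    """
    if ks is None:
        ks = list(range(1, 11))
    ks = sorted(int(k) for k in ks)
    if len(ks) == 0 or ks[0] < 1:
        raise ValueError("ks must be a nonempty list of positive integers")

    if tauE is None:
        tauE = default_readout_time(train_template, ks)
    last_pulse_end = (train_template.tau0 + (max(ks) - 1) * train_template.T
                      + train_template.D)
    if tauE < last_pulse_end:
        raise ValueError(
            f"readout time tauE={tauE} precedes the end of the last pulse "
            f"({last_pulse_end}) of the largest train")

    tau_end = max(tauE, engine.default_horizon(
        PulseTrain(k=max(ks), T=train_template.T, D=train_template.D,
                   tau0=train_template.tau0,
                   amplitude=train_template.amplitude,
                   waveform=train_template.waveform)))

    readouts = []
    if stochastic is not None:
        params = stochastic.params
        root = np.random.default_rng(stochastic.seed)
    for k in ks:
        train = PulseTrain(k=k, T=train_template.T, D=train_template.D,
                           tau0=train_template.tau0,
                           amplitude=train_template.amplitude,
                           waveform=train_template.waveform)
        if stochastic is None:
            traj = engine.integrate(params, train, tau_end,
                                    rtol=rtol, atol=atol)
            readouts.append(engine.endpoint(traj, tauE))
        else:
            vals = []
            for _ in range(stochastic.replicates):
                traj = engine.simulate_stochastic(
                    stochastic, train, tau_end,
                    rng=np.random.default_rng(root.integers(2**31)))
                vals.append(engine.endpoint(traj, tauE))
            readouts.append(float(np.mean(vals)))

    slope_scale = _slope_scale(params, train_template)
    slope, intercept, r2 = linear_fit(ks, readouts, slope_scale=slope_scale)
    return CalibrationCurve(
        ks=tuple(ks), readouts=tuple(readouts), tauE=tauE,
        slope=slope, intercept=intercept, r_squared=r2,
        counting_class=classify_counting(r2, slope),
        params=params, train_template=train_template,
    )


def _slope_scale(params, train: PulseTrain) -> float:
    """Natural per-pulse increment used by the degenerate slope floor."""
    if isinstance(params, IFFLParams):
        return params.beta * train.D * train.amplitude
    if isinstance(params, DimensionalParams):
        return params.k1 * train.D * train.amplitude
    if isinstance(params, VariantParams):
        b = params.beta if params.beta is not None else params.beta_pp
        return b * train.D * train.amplitude
    return 1.0
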