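"""Two-dimensional parameter sweeps of calibration quality.

Each grid cell runs a full calibration curve (simulate k = 1..10 pulses,
read the reporter at a shared fixed time, fit the least-squares line) and
stores its R^2 and slope.  Overlaying the analytic counting border
beta = 1/(1 - e^-D) on the (beta, D) map shows where the simulations flip
from counting (high R^2 below the border) to failure (flat calibration
above it); the (gamma_R, D) map shows the counting range shrinking as the
induced-degradation rate grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import analytics
from .counting import calibration_curve, classify_counting
from .models import IFFLParams
from .signals import PulseTrain

__all__ = ["SweepGrid", "sweep_beta_duration", "sweep_gammaR_duration"]


@dataclass(frozen=True)
class SweepGrid:
    """Per-cell R^2 and slope over a 2-D parameter grid.

    Matrices are shaped (len(axis1_values), len(axis2_values)); cells with
    an invalid train (D >= T) hold NaN.  boundary holds analytic border
    samples as (axis1, axis2) pairs where available.
    """

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    r_squared: np.ndarray
    slope: np.ndarray
    boundary: tuple[tuple[float, float], ...]
    fixed_params: dict = field(default_factory=dict)

    def classification(self) -> np.ndarray:
        """Counting class per cell ('invalid' where not computed)."""
        out = np.full(self.r_squared.shape, "invalid", dtype=object)
        valid = ~np.isnan(self.r_squared)
        for idx in zip(*np.nonzero(valid)):
            out[idx] = classify_counting(self.r_squared[idx])
        return out

    def to_frame(self):
        import pandas as pd

        rows = []
        cls = self.classification()
        for i, a in enumerate(self.axis1_values):
            for j, b in enumerate(self.axis2_values):
                rows.append({
                    self.axis1_name: a,
                    self.axis2_name: b,
                    "r_squared": self.r_squared[i, j],
                    "slope": self.slope[i, j],
                    "class": cls[i, j],
                })
        return pd.DataFrame(rows)


def _run_grid(make_params, axis1_name, axis1_values, D_values,
              T, tau0, ks, tauE, rtol, atol, fixed) -> SweepGrid:
    axis1_values = np.asarray(axis1_values, dtype=float)
    D_values = np.asarray(D_values, dtype=float)
    if axis1_values.size == 0 or D_values.size == 0:
        raise ValueError("sweep ranges must be nonempty")
    r2 = np.full((axis1_values.size, D_values.size), np.nan)
    slope = np.full_like(r2, np.nan)
    for i, a in enumerate(axis1_values):
        params = make_params(a)
        for j, D in enumerate(D_values):
            if not 0 < D < T:
                continue  # invalid cell, left NaN
            train = PulseTrain(k=1, T=T, D=float(D), tau0=tau0)
            curve = calibration_curve(params, train, ks, tauE,
                                      rtol=rtol, atol=atol)
            r2[i, j] = curve.r_squared
            slope[i, j] = curve.slope

    boundary = []
    if axis1_name == "beta":
        for D in D_values:
            if 0 < D < T:
                b = analytics.border_beta(float(D))
                if b <= max(axis1_values) * 1.5:
                    boundary.append((b, float(D)))
    return SweepGrid(
        axis1_name=axis1_name, axis1_values=axis1_values,
        axis2_name="D", axis2_values=D_values,
        r_squared=r2, slope=slope, boundary=tuple(boundary),
        fixed_params=fixed,
    )


def sweep_beta_duration(beta_values: Sequence[float],
                        D_values: Sequence[float],
                        *, gamma_o: float = 0.01, gamma_R: float = 10.0,
                        T: float = 4.0, n: float = 110.0, tau0: float = 1.0,
                        ks: Sequence[int] | None = None,
                        tauE: float | None = None,
                        rtol: float = 1e-8, atol: float = 1e-10) -> SweepGrid:
    """R^2/slope map over synthesis rate beta and pulse duration D.

    Below the analytic border beta = 1/(1 - e^-D) counting is maintained
    (predominantly R^2 >= 0.99); above it the calibration is flat and
    counting fails.  Cells with beta <= 1 count at every duration — the
    network cannot discriminate signals there.
    """
    fixed = {"gamma_o": gamma_o, "gamma_R": gamma_R, "T": T, "n": n,
             "tau0": tau0}
    return _run_grid(
        lambda b: IFFLParams(beta=float(b), gamma_R=gamma_R,
                             gamma_o=gamma_o, n=n),
        "beta", beta_values, D_values, T, tau0, ks, tauE, rtol, atol, fixed)


def sweep_gammaR_duration(gammaR_values: Sequence[float],
                          D_values: Sequence[float],
                          *, beta: float = 1.2, gamma_o: float = 0.01,
                          T: float = 4.0, n: float = 110.0, tau0: float = 1.0,
                          ks: Sequence[int] | None = None,
                          tauE: float | None = None,
                          rtol: float = 1e-8, atol: float = 1e-10) -> SweepGrid:
    """R^2/slope map over induced-degradation rate gamma_R and duration D.

    As gamma_R decreases the intermediate loses its grip on the reporter
    and the network stops discriminating pulsed from sustained inputs;
    as gamma_R increases the counting duration range shrinks.
    """
    fixed = {"beta": beta, "gamma_o": gamma_o, "T": T, "n": n, "tau0": tau0}
    return _run_grid(
        lambda g: IFFLParams(beta=beta, gamma_R=float(g),
                             gamma_o=gamma_o, n=n),
        "gamma_R", gammaR_values, D_values, T, tau0, ks, tauE, rtol, atol,
        fixed)
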