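"""Numerical integration of the IFFL models over pulse trains.

Deterministic trajectories are produced by piecewise integration: the input
signal is discontinuous at every pulse edge, so the solver is restarted at
each edge with the previous endpoint as the initial condition.  The forcing
then never crosses a solver step, and the stored time grid contains every
edge exactly.  Within a segment a stiff-capable method is used — the
switch-like induced-degradation term (Hill coefficient ~110) makes the
reporter equation extremely stiff whenever the intermediate crosses its
threshold.

Stochastic trajectories use fixed-step Euler–Maruyama on molecular numbers
with additive Gaussian white noise of amplitude xi on each species, clamped
at zero from below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .models import (
    DimensionalParams,
    IFFLParams,
    VariantParams,
    base_derivatives,
    dimensional_derivatives,
    variant_derivatives,
)
from .signals import PulseTrain

__all__ = [
    "Trajectory",
    "StochasticConfig",
    "IntegrationError",
    "integrate",
    "endpoint",
    "cycle_extrema",
    "simulate_stochastic",
    "default_horizon",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
#: spacing of stored samples within each inter-edge segment
DEFAULT_STORE_STEP = 0.02


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails inside a segment."""


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped state of all species from one simulation.

    species maps a state-variable name (e.g. ``x``, ``r``, ``X``, ``R``)
    to a sample array aligned with ``times``.
    """

    times: np.ndarray
    species: dict[str, np.ndarray]
    params: object = None
    train: PulseTrain | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, vals in self.species.items():
            if len(vals) != len(self.times):
                raise ValueError(
                    f"species {name!r} has {len(vals)} samples for "
                    f"{len(self.times)} time points")

    @property
    def reporter_name(self) -> str:
        # reporter is always the last state variable
        return list(self.species)[-1]

    @property
    def intermediate_name(self) -> str:
        for cand in ("x", "X"):
            if cand in self.species:
                return cand
        raise KeyError("trajectory has no intermediate species 'x' or 'X'")

    def value_at(self, name: str, tau) -> float | np.ndarray:
        out = np.interp(tau, self.times, self.species[name])
        return float(out) if np.ndim(tau) == 0 else out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, **self.species})


@dataclass(frozen=True)
class StochasticConfig:
    """Configuration of the Langevin (molecular-number) simulation.

    xi is the noise amplitude: each species' rate equation gains an
    additive white-noise term of standard deviation ``xi*sqrt(dt)`` per
    step.  dt is the fixed Euler–Maruyama step.
    """

    params: DimensionalParams
    xi: float = 10.0
    dt: float | None = None  # default D/100 of the driving train
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.xi < 0:
            raise ValueError("xi must be nonnegative")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def default_horizon(train: PulseTrain) -> float:
    """Default integration horizon: one quiet cycle after the last pulse."""
    n = max(train.k, 1) if train.waveform != "sustained" else 1
    T = train.T if train.waveform != "sustained" else train.D
    return train.tau0 + n * T + T


def _rhs_for(params) -> tuple:
    """(state names, derivative function f(t, y, input_level)) per model."""
    if isinstance(params, IFFLParams):
        return ("x", "r"), lambda t, y, u: base_derivatives(y, t, params, u)
    if isinstance(params, DimensionalParams):
        return (("X", "R"),
                lambda t, y, u: dimensional_derivatives(y, t, params, u))
    if isinstance(params, VariantParams):
        return (params.state_names,
                lambda t, y, u: variant_derivatives(y, t, params, u))
    raise TypeError(f"unsupported parameter object {type(params).__name__}")


def _segments(train: PulseTrain, tau_end: float) -> list[tuple[float, float]]:
    edges = [e for e in train.edges() if 0.0 < e < tau_end]
    pts = [0.0] + sorted(set(edges)) + [tau_end]
    return [(a, b) for a, b in zip(pts[:-1], pts[1:]) if b > a]


def integrate(
    params,
    train: PulseTrain,
    tau_end: float | None = None,
    *,
    y0=None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    store_step: float = DEFAULT_STORE_STEP,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate a model over a pulse train, restarting at every pulse edge.

    Parameters
    ----------
    params : IFFLParams | DimensionalParams | VariantParams
        Selects the model (base dimensionless, dimensional, or a variant).
    train : PulseTrain
        Driving input; the model consumes ``amplitude * Phi``.
    tau_end : float, optional
        Integration horizon; defaults to one quiet cycle after the last
        pulse.
    y0 : sequence, optional
        Initial state; defaults to the origin (all species at rest).
    """
    names, rhs = _rhs_for(params)
    if tau_end is None:
        tau_end = default_horizon(train)
    if tau_end <= 0:
        raise ValueError(f"tau_end must be positive, got {tau_end}")
    if y0 is None:
        y0 = np.zeros(len(names))
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (len(names),):
        raise ValueError(
            f"initial state must have {len(names)} components, got {y0.shape}")

    times = [0.0]
    states = [y0.copy()]
    y = y0
    for a, b in _segments(train, tau_end):
        # input evaluated strictly inside the segment: constant for square
        # trains, smooth for sine
        mid = 0.5 * (a + b)
        if train.waveform == "sine":
            f = lambda t, yy: rhs(t, yy, train(t))
        else:
            u = train(mid)
            f = lambda t, yy, u=u: rhs(t, yy, u)
        npts = max(2, int(math.ceil((b - a) / store_step)) + 1)
        t_eval = np.linspace(a, b, npts)
        sol = solve_ivp(f, (a, b), y, method=method, t_eval=t_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"solver failed on segment [{a}, {b}]: {sol.message}")
        times.extend(sol.t[1:].tolist())
        states.extend(list(sol.y[:, 1:].T))
        y = sol.y[:, -1]

    arr = np.asarray(states)
    t = np.asarray(times)
    species = {name: arr[:, j].copy() for j, name in enumerate(names)}
    return Trajectory(
        times=t, species=species, params=params, train=train,
        meta={"rtol": rtol, "atol": atol, "method": method},
    )


def endpoint(trajectory: Trajectory, tauE: float) -> float:
    """Reporter level r(tauE), linearly interpolated from stored samples."""
    if tauE < trajectory.times[0] or tauE > trajectory.times[-1]:
        raise ValueError(
            f"tauE={tauE} outside the trajectory span "
            f"[{trajectory.times[0]}, {trajectory.times[-1]}]")
    return trajectory.value_at(trajectory.reporter_name, tauE)


def cycle_extrema(trajectory: Trajectory,
                  train: PulseTrain | None = None,
                  ) -> tuple[list[float], list[float]]:
    """Per-pulse (peaks, basals) of the intermediate.

    peak_i is the intermediate at the end of pulse i's ON window (where a
    driven first-order species is maximal); basal_i is its level at the
    window start.  Lists have length k.
    """
    if train is None:
        train = trajectory.train
    if train is None:
        raise ValueError("no pulse train associated with the trajectory")
    if train.end_time > trajectory.times[-1] + 1e-12:
        raise ValueError("trajectory does not cover the full pulse train")
    name = trajectory.intermediate_name
    peaks, basals = [], []
    for a, b in train.windows():
        basals.append(trajectory.value_at(name, a))
        peaks.append(trajectory.value_at(name, b))
    return peaks, basals


def simulate_stochastic(config: StochasticConfig, train: PulseTrain,
                        tau_end: float | None = None,
                        *, rng: np.random.Generator | None = None,
                        ) -> Trajectory:
    """One Euler–Maruyama replicate of the molecular-number model.

    Each species' deterministic rate gains an additive Gaussian white-noise
    term of amplitude xi; species are clamped at zero from below after each
    step.  Identical seed gives an identical trajectory.
    """
    p = config.params
    dt = config.dt if config.dt is not None else train.D / 100.0
    if dt * p.dx >= 0.5:
        raise ValueError(
            f"dt={dt} too large for degradation rate dx={p.dx} "
            "(explicit stepping unstable); decrease dt")
    if dt > train.D / 10.0:
        raise ValueError(
            f"dt={dt} must resolve the pulse duration (need dt < D/10 = "
            f"{train.D / 10.0})")
    if tau_end is None:
        tau_end = default_horizon(train)
    if rng is None:
        rng = np.random.default_rng(config.seed)

    nsteps = int(math.ceil(tau_end / dt))
    times = np.linspace(0.0, nsteps * dt, nsteps + 1)
    X = np.empty(nsteps + 1)
    R = np.empty(nsteps + 1)
    X[0] = R[0] = 0.0
    sqdt = math.sqrt(dt)
    noise = rng.standard_normal((nsteps, 2))
    for i in range(nsteps):
        t = times[i]
        u = train(t)
        dX, dR = dimensional_derivatives((X[i], R[i]), t, p, u)
        X[i + 1] = max(0.0, X[i] + dX * dt + config.xi * sqdt * noise[i, 0])
        R[i + 1] = max(0.0, R[i] + dR * dt + config.xi * sqdt * noise[i, 1])

    return Trajectory(
        times=times, species={"X": X, "R": R}, params=p, train=train,
        meta={"xi": config.xi, "dt": dt, "seed": config.seed},
    )
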