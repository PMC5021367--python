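"""Input signals for the IFFL: square pulse trains, half-sine pulse trains,
and sustained steps.

The driving signal Phi(tau) is a train of ``k`` pulses of duration ``D``
repeating with cycle period ``T``, the first pulse starting at ``tau0``.
During the ON phase of pulse ``i`` (window ``[i*T + tau0, i*T + D + tau0)``)
a square train takes the value ``amplitude``; a sine train traces a half-sine
arch ``amplitude * sin(pi * (tau - start) / D)`` so that the signal vanishes
at every window boundary.  A sustained input is a single step of length ``D``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np

__all__ = [
    "PulseTrain",
    "evaluate_input",
    "pulse_windows",
    "sustained_equivalent_amplitude",
]

_WAVEFORMS = ("square", "sine", "sustained")


@dataclass(frozen=True)
class PulseTrain:
    """A pulsatile (or sustained) input signal.

    Parameters
    ----------
    k : int
        Number of pulses (ignored for ``sustained``, which is one step).
    T : float
        Cycle period: time between the start points of adjacent pulses.
    D : float
        Pulse duration (ON length). Must satisfy ``0 < D < T`` for
        oscillatory waveforms; for ``sustained`` it is the total ON length.
    tau0 : float
        Start time of the first pulse. Defaults to 1, the convention used
        throughout for simulations.
    amplitude : float
        Input level during the ON phase.
    waveform : {"square", "sine", "sustained"}
    """

    k: int = 1
    T: float = 4.0
    D: float = 1.0
    tau0: float = 1.0
    amplitude: float = 1.0
    waveform: str = "square"

    def __post_init__(self) -> None:
        if self.waveform not in _WAVEFORMS:
            raise ValueError(
                f"waveform must be one of {_WAVEFORMS}, got {self.waveform!r}"
            )
        if self.k < 0:
            raise ValueError(f"k must be a nonnegative integer, got {self.k}")
        if self.D <= 0:
            raise ValueError(f"D must be positive, got {self.D}")
        if self.tau0 < 0:
            raise ValueError(f"tau0 must be nonnegative, got {self.tau0}")
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        if self.waveform in ("square", "sine") and not self.D < self.T:
            raise ValueError(
                f"pulse duration D={self.D} must be smaller than the cycle "
                f"period T={self.T} for waveform {self.waveform!r}"
            )

    # -- window bookkeeping -------------------------------------------------

    @property
    def n_windows(self) -> int:
        return 1 if self.waveform == "sustained" else self.k

    @property
    def end_time(self) -> float:
        """Time at which the signal is permanently off."""
        if self.waveform == "sustained":
            return self.tau0 + self.D
        if self.k == 0:
            return self.tau0
        return self.tau0 + (self.k - 1) * self.T + self.D

    def windows(self) -> list[tuple[float, float]]:
        return pulse_windows(self)

    def edges(self) -> list[float]:
        """Sorted pulse edge times (window starts and ends)."""
        out: list[float] = []
        for a, b in pulse_windows(self):
            out.append(a)
            out.append(b)
        return out

    def __call__(self, tau) -> np.ndarray | float:
        return evaluate_input(self, tau)

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "PulseTrain":
        return cls(**mapping)


def pulse_windows(train: PulseTrain) -> list[tuple[float, float]]:
    """Ordered ON windows ``(start, end)`` of a train; empty for ``k=0``.

    Windows are half-open ``[start, end)``: the end instant itself carries
    Phi = 0.
    """
    if train.waveform == "sustained":
        return [(train.tau0, train.tau0 + train.D)]
    return [
        (i * train.T + train.tau0, i * train.T + train.D + train.tau0)
        for i in range(train.k)
    ]


def evaluate_input(train: PulseTrain, tau) -> np.ndarray | float:
    """Signal level Phi(tau); accepts scalars or arrays.

    Square trains return ``amplitude`` inside an ON window and 0 elsewhere;
    sine trains return ``amplitude * sin(pi*(tau - start)/D)`` inside a
    window; sustained inputs are a single step on ``[tau0, tau0 + D)``.
    """
    t = np.asarray(tau, dtype=float)
    out = np.zeros_like(t)
    if train.waveform == "sustained":
        on = (t >= train.tau0) & (t < train.tau0 + train.D)
        out[on] = train.amplitude
    else:
        # relative position within the current cycle
        rel = t - train.tau0
        idx = np.floor(rel / train.T)
        phase = rel - idx * train.T
        on = (idx >= 0) & (idx < train.k) & (phase < train.D)
        if train.waveform == "square":
            out[on] = train.amplitude
        else:  # sine: half-sine arch over the ON window
            out[on] = train.amplitude * np.sin(np.pi * phase[on] / train.D)
    if np.isscalar(tau) or np.ndim(tau) == 0:
        return float(out)
    return out


def sustained_equivalent_amplitude(train: PulseTrain, horizon: float) -> float:
    """Time-average of Phi over ``[0, horizon]``.

    The mean level of an oscillating input over a finite horizon — the
    amplitude a sustained input must take to deliver the same average drive.
    For a square train whose pulses all fit inside the horizon this is
    ``k * D * amplitude / horizon``; for an infinitely repeated square wave
    sampled over whole cycles it reduces to the duty-cycle mean
    ``amplitude * D / T``.
    """
    if horizon <= train.tau0:
        raise ValueError(
            f"horizon ({horizon}) must exceed the train start tau0 ({train.tau0})"
        )
    total = 0.0
    for a, b in pulse_windows(train):
        a_c, b_c = max(a, 0.0), min(b, horizon)
        if b_c <= a_c:
            continue
        if train.waveform == "sine":
            # integral of amplitude*sin(pi*(tau-a)/D) over the clipped window
            w = train.D / math.pi
            total += train.amplitude * w * (
                math.cos(math.pi * (a_c - a) / train.D)
                - math.cos(math.pi * (b_c - a) / train.D)
            )
        else:
            total += train.amplitude * (b_c - a_c)
    return total / horizon
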