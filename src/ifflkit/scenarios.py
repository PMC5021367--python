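"""Scenario configuration, dispatch and serialization.

A :class:`ScenarioConfig` is a flat, YAML/JSON-serializable description of
one analysis: which model, which parameters (keyed by the standard symbol
names: beta, gamma_R, gamma_o, n, k1, ...), which input train, and exactly
one analysis request (simulate | calibrate | capacity | border | sweep).
:func:`run` dispatches it to the library and writes CSV data plus a JSON
metadata summary; identical config and seed give identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__, analytics, engine, sweeps
from .counting import calibration_curve
from .engine import StochasticConfig
from .models import DimensionalParams, IFFLParams, VariantParams
from .signals import PulseTrain

__all__ = ["ScenarioConfig", "run", "ConfigError"]

log = logging.getLogger("ifflkit")

_MODELS = ("base", "dimensional", "stochastic", "positive_feedback",
           "delay_inhibition", "delay_activation", "repression")
_ANALYSES = ("simulate", "calibrate", "capacity", "border", "sweep")


class ConfigError(ValueError):
    """A scenario configuration failed validation; names the bad field."""


@dataclass(frozen=True)
class ScenarioConfig:
    """One self-contained analysis scenario."""

    model: str = "base"
    analysis: str = "simulate"
    params: dict = field(default_factory=dict)
    #: one train mapping, or a list of mappings (simulate only)
    train: dict | list = field(default_factory=dict)
    ks: tuple | None = None
    tauE: float | None = None
    tau_end: float | None = None
    seed: int = 0
    xi: float = 10.0
    dt: float | None = None
    replicates: int = 1
    rtol: float = engine.DEFAULT_RTOL
    atol: float = engine.DEFAULT_ATOL
    #: Hill coefficients to repeat a calibration over (robustness scan)
    n_values: tuple | None = None
    #: sweep request: axis ("beta"|"gamma_R"), axis_values, D_values, fixed
    sweep: dict | None = None
    #: border request: betas, T_values
    border: dict | None = None
    description: str = ""

    # -- validation and object construction ---------------------------------

    def validate(self) -> None:
        if self.model not in _MODELS:
            raise ConfigError(f"model: must be one of {_MODELS}, "
                              f"got {self.model!r}")
        if self.analysis not in _ANALYSES:
            raise ConfigError(f"analysis: must be one of {_ANALYSES}, "
                              f"got {self.analysis!r}")
        if self.analysis not in ("border", "capacity", "sweep"):
            for tr in self.trains():
                try:
                    PulseTrain.from_dict(tr)
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"train: {exc}") from exc
            try:
                self.model_params()
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"params: {exc}") from exc
        if self.analysis == "sweep" and not self.sweep:
            raise ConfigError("sweep: missing sweep request mapping")
        if self.analysis == "border" and not self.border:
            raise ConfigError("border: missing border request mapping")

    def trains(self) -> list[dict]:
        return self.train if isinstance(self.train, list) else [self.train]

    def model_params(self):
        if self.model == "base":
            return IFFLParams.from_dict(self.params)
        if self.model in ("dimensional", "stochastic"):
            return DimensionalParams.from_dict(self.params)
        return VariantParams.from_dict({"variant": self.model, **self.params})

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: v for k, v in d.items() if v not in (None, {}, "", [])}

    @classmethod
    def from_dict(cls, mapping: dict) -> "ScenarioConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        for key in ("ks", "n_values"):
            if key in mapping and mapping[key] is not None:
                mapping = {**mapping, key: tuple(mapping[key])}
        return cls(**mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, float) and np.isinf(o):
        return "inf"
    raise TypeError(f"not JSON serializable: {type(o)}")


def run(config: ScenarioConfig, outdir: str | Path) -> dict:
    """Execute a scenario, write artifacts under outdir, return the summary.

    Artifacts: CSV data files per analysis plus ``meta.json`` holding the
    config, seed, solver tolerances, package version and the summary.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("running scenario: model=%s analysis=%s seed=%d",
             config.model, config.analysis, config.seed)

    summary: dict = {}
    if config.analysis == "simulate":
        summary["trajectories"] = []
        for idx, tr_map in enumerate(config.trains()):
            train = PulseTrain.from_dict(tr_map)
            if config.model == "stochastic":
                sc = StochasticConfig(params=config.model_params(),
                                      xi=config.xi, dt=config.dt,
                                      seed=config.seed,
                                      replicates=config.replicates)
                traj = engine.simulate_stochastic(sc, train, config.tau_end)
            else:
                traj = engine.integrate(config.model_params(), train,
                                        config.tau_end, rtol=config.rtol,
                                        atol=config.atol)
            stem = "trajectory" if len(config.trains()) == 1 \
                else f"trajectory_{idx}"
            traj.to_frame().to_csv(outdir / f"{stem}.csv", index=False)
            summary["trajectories"].append({
                "file": f"{stem}.csv", "train": tr_map,
                "final": {k: float(v[-1]) for k, v in traj.species.items()},
            })

    elif config.analysis == "calibrate":
        train = PulseTrain.from_dict(config.trains()[0])
        n_values = config.n_values or (None,)
        curves = []
        for n in n_values:
            params = config.model_params()
            if n is not None:
                params = _with_n(params, n)
            if config.model == "stochastic":
                sc = StochasticConfig(params=params, xi=config.xi,
                                      dt=config.dt, seed=config.seed,
                                      replicates=config.replicates)
                curve = calibration_curve(None, train, config.ks,
                                          config.tauE, stochastic=sc)
            else:
                curve = calibration_curve(params, train, config.ks,
                                          config.tauE, rtol=config.rtol,
                                          atol=config.atol)
            curves.append((n, curve))
        stem = "calibration"
        for n, curve in curves:
            name = stem if n is None else f"{stem}_n{n:g}"
            curve.to_frame().to_csv(outdir / f"{name}.csv", index=False)
        if config.n_values:
            summary["curves"] = {f"n={n:g}": c.summary() for n, c in curves}
        else:
            summary.update(curves[0][1].summary())

    elif config.analysis == "capacity":
        p = config.params
        res = analytics.counting_capacity(p["beta"], p["T"], p["D"],
                                          int(p.get("max_pulses", 1000)))
        import pandas as pd

        pd.DataFrame({"pulse": np.arange(1, len(res.peaks) + 1),
                      "peak": res.peaks, "basal": res.basals}
                     ).to_csv(outdir / "capacity.csv", index=False)
        summary.update({"nc": res.nc, "indefinite": res.is_indefinite})

    elif config.analysis == "border":
        import pandas as pd

        req = config.border
        rows = []
        for beta in req["betas"]:
            for T in req["T_values"]:
                ratio = analytics.relative_duration_border(beta, T)
                rows.append({"beta": beta, "T": T, "D": ratio * T,
                             "D_over_T": ratio})
        pd.DataFrame(rows).to_csv(outdir / "border.csv", index=False)
        summary["n_points"] = len(rows)

    elif config.analysis == "sweep":
        req = dict(config.sweep)
        axis = req.pop("axis")
        axis_values = np.asarray(req.pop("axis_values"), dtype=float)
        D_values = np.asarray(req.pop("D_values"), dtype=float)
        req.setdefault("ks", config.ks)
        if axis == "beta":
            grid = sweeps.sweep_beta_duration(axis_values, D_values, **req)
        elif axis == "gamma_R":
            grid = sweeps.sweep_gammaR_duration(axis_values, D_values, **req)
        else:
            raise ConfigError(f"sweep.axis: must be 'beta' or 'gamma_R', "
                              f"got {axis!r}")
        grid.to_frame().to_csv(outdir / "sweep.csv", index=False)
        if grid.boundary:
            import pandas as pd

            pd.DataFrame(grid.boundary, columns=[grid.axis1_name, "D"]
                         ).to_csv(outdir / "boundary.csv", index=False)
        cls = grid.classification()
        summary["n_cells"] = int(np.sum(cls != "invalid"))
        summary["n_high_quality"] = int(np.sum(cls == "high_quality"))
        summary["n_failure"] = int(np.sum(cls == "failure"))

    meta = {
        "config": config.to_dict(),
        "seed": config.seed,
        "tolerances": {"rtol": config.rtol, "atol": config.atol},
        "version": __version__,
        "summary": summary,
    }
    _write_json(outdir / "meta.json", meta)
    return summary


def _with_n(params, n: float):
    if isinstance(params, IFFLParams):
        return IFFLParams(beta=params.beta, gamma_R=params.gamma_R,
                          gamma_o=params.gamma_o, n=n)
    if isinstance(params, DimensionalParams):
        return DimensionalParams.from_dict({**params.to_dict(), "n": n})
    d = params.to_dict()
    d["n"] = n
    return VariantParams.from_dict(d)
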