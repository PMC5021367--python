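"""Packaged scenarios carrying the exact caption parameter sets.

Every built-in study condition is expressed as a :class:`ScenarioConfig`
so that each one can be re-run end-to-end from the command line
(``ifflkit run <name>``) or from Python (``scenarios.run(FIXTURES[name],
outdir)``).
"""

from __future__ import annotations

from .scenarios import ScenarioConfig

__all__ = ["FIXTURES", "list_fixtures", "get_fixture"]

_BASE = {"beta": 1.2, "gamma_R": 10.0, "gamma_o": 0.0, "n": 110.0}
_TRAIN = {"T": 4.0, "D": 1.0, "tau0": 1.0}


def _train(**over) -> dict:
    return {**_TRAIN, **over}


FIXTURES: dict[str, ScenarioConfig] = {
    "fig2b_left": ScenarioConfig(
        model="base", analysis="simulate", params=dict(_BASE),
        train=_train(k=4),
        description="Counting time course: short pulses (D=1) keep the "
                    "intermediate sub-threshold and the reporter steps up "
                    "with each pulse."),
    "fig2b_right": ScenarioConfig(
        model="base", analysis="simulate", params=dict(_BASE),
        train=_train(k=4, D=3.0),
        description="Resetting time course: long pulses (D=3) push the "
                    "intermediate over threshold and the reporter is reset "
                    "each cycle."),
    "fig2c": ScenarioConfig(
        model="base", analysis="calibrate", params=dict(_BASE),
        train=_train(k=1), ks=(1, 2, 3, 4),
        description="Ideal counting calibration over 1-4 pulses "
                    "(R^2 >= 0.99)."),
    "fig3a": ScenarioConfig(
        model="base", analysis="calibrate",
        params={**_BASE, "gamma_o": 0.01},
        train=_train(k=1), ks=tuple(range(1, 11)),
        description="High-quality counting with a slightly unstable "
                    "reporter (gamma_o=0.01), 1-10 pulses."),
    "fig3b": ScenarioConfig(
        model="base", analysis="calibrate",
        params={**_BASE, "gamma_o": 0.05},
        train=_train(k=1), ks=tuple(range(1, 11)),
        description="Low-quality counting with a highly unstable reporter "
                    "(gamma_o=0.05): 0 < R^2 < 0.99."),
    "fig4a": ScenarioConfig(
        model="base", analysis="sweep", ks=tuple(range(1, 11)),
        sweep={"axis": "beta",
               "axis_values": [0.25 * i for i in range(17)],
               "D_values": [0.25 * i for i in range(1, 16)],
               "gamma_o": 0.01, "gamma_R": 10.0, "T": 4.0},
        description="R^2/slope map over beta (0-4) and duration (0-4) at "
                    "T=4, gamma_o=0.01, with the analytic border "
                    "beta=1/(1-e^-D). Coarser 0.25 grid; pass a finer grid "
                    "via the CLI for publication-resolution maps."),
    "fig4c": ScenarioConfig(
        model="base", analysis="sweep", ks=tuple(range(1, 11)),
        sweep={"axis": "gamma_R",
               "axis_values": [0.25 * i for i in range(13)],
               "D_values": [0.25 * i for i in range(1, 16)],
               "beta": 1.2, "gamma_o": 0.01, "T": 4.0},
        description="R^2/slope map over gamma_R (0-3) and duration (0-4) "
                    "at beta=1.2, T=4, gamma_o=0.01."),
    "fig5": ScenarioConfig(
        analysis="border",
        border={"betas": [12.0, 2.0, 1.2],
                "T_values": [0.5 * i for i in range(1, 41)]},
        description="Relative-duration border D/T solving "
                    "(1-e^-D)/(1-e^-T)=1/beta for beta in {12, 2, 1.2}."),
    "s1_sine": ScenarioConfig(
        model="base", analysis="calibrate", params=dict(_BASE),
        train=_train(k=1, waveform="sine"), ks=(1, 2, 3, 4),
        description="Counting is preserved for half-sine pulses "
                    "(same parameters as the ideal square-wave case)."),
    "s2_fail": ScenarioConfig(
        model="base", analysis="calibrate", params=dict(_BASE),
        train=_train(k=1, D=3.0), ks=tuple(range(1, 11)),
        description="Failed counting for long pulses (D=3): flat "
                    "calibration, R^2 reported as 0."),
    "s3_posfeedback": ScenarioConfig(
        model="positive_feedback", analysis="calibrate",
        params={"beta": 1.2, "gamma_R": 0.01, "gamma_o": 0.0,
                "alpha": 100.0, "n": 110.0},
        train={"T": 10.0, "D": 1.0, "tau0": 1.0, "k": 1},
        ks=tuple(range(1, 11)),
        description="Positive-feedback ultrasensitivity variant: counting "
                    "at D=1, T=10 (failure at D=9)."),
    "s4_delay_inhibition": ScenarioConfig(
        model="delay_inhibition", analysis="simulate",
        params={"beta_p": 1.0, "beta_pp": 1.2, "gamma_R": 10.0,
                "delta": 1.0, "gamma_o": 0.0, "n": 110.0},
        train=[_train(k=4), _train(k=4, D=3.0)],
        description="Delay in the inhibition arm (input -> x1 -> X): "
                    "counting at D=1, resetting at D=3."),
    "s5_delay_activation": ScenarioConfig(
        model="delay_activation", analysis="simulate",
        params={"beta_p": 5.0, "beta_pp": 1.2, "gamma_R": 10.0,
                "gamma_R1": 5.0, "gamma_o": 0.0, "n": 110.0},
        train=[_train(k=4), _train(k=4, D=3.0)],
        description="Delay in the activation arm (input -> r1 -> R): "
                    "counting at D=1, resetting at D=3."),
    "s6_equal_mean": ScenarioConfig(
        model="base", analysis="simulate",
        params={"beta": 0.337, "gamma_R": 10.0, "gamma_o": 0.0, "n": 110.0},
        train={"waveform": "sustained", "D": 40.0, "tau0": 1.0, "T": 4.0,
               "k": 1},
        description="Sustained input whose level (0.337) matches the mean "
                    "of the D=1, T=4 oscillating input: no stepwise "
                    "response."),
    "s7_hill_scan": ScenarioConfig(
        model="base", analysis="calibrate", params=dict(_BASE),
        train=_train(k=1), ks=(1, 2, 3, 4),
        n_values=(5.0, 50.0, 110.0, 1000.0),
        description="Hill-coefficient robustness: the counting class is "
                    "insensitive to n as long as the threshold response is "
                    "steep."),
    "s8_stochastic_low": ScenarioConfig(
        model="stochastic", analysis="calibrate",
        params={"k1": 5.0, "k2": 5.0, "dx": 1.0, "dR": 10.0, "dRo": 0.0,
                "Kx": 4.0, "n": 100.0},
        train=_train(k=1), ks=tuple(range(1, 11)), xi=10.0, seed=0,
        description="Langevin model at low molecule numbers (k1=k2=5, "
                    "Kx=4, xi=10): noise destroys counting, R^2 < 0.99."),
    "s8_stochastic_mid": ScenarioConfig(
        model="stochastic", analysis="calibrate",
        params={"k1": 50.0, "k2": 50.0, "dx": 1.0, "dR": 10.0, "dRo": 0.0,
                "Kx": 40.0, "n": 100.0},
        train=_train(k=1), ks=tuple(range(1, 11)), xi=10.0, seed=0,
        description="Langevin model at intermediate molecule numbers "
                    "(k1=k2=50, Kx=40, xi=10)."),
    "s8_stochastic_high": ScenarioConfig(
        model="stochastic", analysis="calibrate",
        params={"k1": 500.0, "k2": 500.0, "dx": 1.0, "dR": 10.0,
                "dRo": 0.0, "Kx": 400.0, "n": 100.0},
        train=_train(k=1), ks=tuple(range(1, 11)), xi=10.0, seed=0,
        description="Langevin model at high molecule numbers (k1=k2=500, "
                    "Kx=400, xi=10): counting survives, R^2 >= 0.99."),
    "s9_repression": ScenarioConfig(
        model="repression", analysis="simulate",
        params={"beta": 12.0, "gamma_o": 0.0, "n": 110.0},
        train=[_train(k=4), _train(k=4, D=3.0)],
        description="Threshold implemented as repression of R production "
                    "(beta=12): stepwise counting at D=1, shutdown at "
                    "D=3."),
}


def list_fixtures() -> dict[str, str]:
    """Names and one-line descriptions of the packaged scenarios."""
    return {name: cfg.description for name, cfg in FIXTURES.items()}


def get_fixture(name: str) -> ScenarioConfig:
    try:
        return FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
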