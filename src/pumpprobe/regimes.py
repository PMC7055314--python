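"""Control-regime simulation and classification for pump-probe networks.

A pump-probe network can operate in qualitatively different sensory modes
depending on the balance between per-cell production and uptake capacity:

* **quorum**: net production ``pi_eff = f*pi - v_max > 0``; extracellular
  signal tracks population density and the output rises with both inoculum
  and producer fraction.
* **ratiometric**: ``pi_eff < 0``; the extracellular concentration relaxes to
  a density-independent steady state set only by the producer fraction ``f``.
* **chronometric**: import is saturated (extracellular signal far above K_M)
  and transduction is switch-like (large Hill coefficient); the output
  crosses its threshold after a delay set by cellular parameters, largely
  independent of the social context.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import (
    ModelParameters,
    N_AVOGADRO,
    SignalState,
    Trajectory,
    cells_from_od,
    fret_response,
    hill_output,
    simulate,
    steady_state_ratiometric,
)

# Illustrative parameter sets for the three regimes (growing population in
# 10 mL at 0.55/h).  Particle rates converted from the molar per-cell fluxes
# 0.31 amol/min (uptake) and 1 amol / 1 zmol / 10 amol per min (production).
_V_MAX_FIG = 0.31e-18 * N_AVOGADRO  # ~1.87e5 molecules/min
_MU_FIG = 0.55 / 60.0


def quorum_params(f: float = 1.0) -> ModelParameters:
    """Parameter set producing quorum-sensing control (net production > 0)."""
    return ModelParameters(
        v_max=_V_MAX_FIG, K_M=1.40e-3, pi=1e-18 * N_AVOGADRO, f=f,
        lambda_e=0.1, lambda_i=0.1, mu=_MU_FIG, V_e=10e-3,
        EC50=0.37e-6, n=1.0,
    )


def ratiometric_params(f: float = 1.0) -> ModelParameters:
    """Parameter set producing ratiometric (fractional) sensing."""
    return ModelParameters(
        v_max=_V_MAX_FIG, K_M=140e-9, pi=1e-21 * N_AVOGADRO, f=f,
        lambda_e=0.0, lambda_i=0.1, mu=_MU_FIG, V_e=10e-3,
        EC50=8.5e-6, n=1.0,
    )


def chronometric_params(f: float = 1.0, lambda_i: float = 1e-4) -> ModelParameters:
    """Parameter set producing chronometric (delay-timer) control."""
    return ModelParameters(
        v_max=_V_MAX_FIG, K_M=140e-9, pi=10e-18 * N_AVOGADRO, f=f,
        lambda_e=0.0, lambda_i=lambda_i, mu=_MU_FIG, V_e=10e-3,
        EC50=29e-3, n=10.0,
    )


@dataclass
class ScenarioConfig:
    """Grid of growth scenarios: inoculum densities x producer fractions."""

    params: ModelParameters
    inoculum_od: tuple[float, ...] = (0.0125, 0.0063)
    f_values: tuple[float, ...] = (1.0, 0.5, 0.25)
    horizon: float = 720.0  # minutes
    output_mode: str = "hill"  # or "fret"
    n_points: int = 400

    def __post_init__(self):
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if any(not 0 <= f <= 1 for f in self.f_values):
            raise ValueError("all producer fractions must lie in [0, 1]")
        if self.output_mode not in ("hill", "fret"):
            raise ValueError("output_mode must be 'hill' or 'fret'")


@dataclass
class RegimeLabel:
    label: str  # quorum | ratiometric | chronometric | indeterminate
    pi_eff: float  # molecules/min
    delay: float | None = None

    def __post_init__(self):
        if self.label == "quorum" and not self.pi_eff > 0:
            raise ValueError("quorum label requires pi_eff > 0")
        if self.label == "ratiometric" and not self.pi_eff < 0:
            raise ValueError("ratiometric label requires pi_eff < 0")


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    trajectories: dict  # (od, f) -> Trajectory
    outputs: dict  # (od, f) -> np.ndarray of O(t)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (od, f), traj in self.trajectories.items():
            out = self.outputs[(od, f)]
            rows.append(
                pd.DataFrame(
                    {
                        "inoculum_od": od,
                        "f": f,
                        "t_min": traj.time_grid,
                        "Ce_M": traj.C_e_s,
                        "Ci_M": traj.C_i_s,
                        "O": out,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Simulate the scenario grid; producers start at t=0 with no signal."""
    p = config.params
    grid = np.linspace(0.0, config.horizon, config.n_points)
    trajectories, outputs = {}, {}
    for od in config.inoculum_od:
        for f in config.f_values:
            params = p.with_(f=f)
            nc0 = cells_from_od(od, params.V_e)
            init = SignalState(t=0.0, C_i_s=0.0, C_e_s=0.0, C_e_tot=0.0, N_c=nc0)
            traj = simulate(params, init, grid)
            if config.output_mode == "hill":
                out = hill_output(traj.C_i_s, params)
            else:
                out = fret_response(traj.C_i_s, params)
            trajectories[(od, f)] = traj
            outputs[(od, f)] = np.asarray(out)
    return ScenarioResult(config=config, trajectories=trajectories, outputs=outputs)


def classify_regime(
    params: ModelParameters,
    c_e0: float = 0.0,
    n_switch: float = 5.0,
    saturation_margin: float = 0.95,
) -> RegimeLabel:
    """Classify the control regime from the parameter set.

    Chronometric requires switch-like transduction (n >= ``n_switch``) and a
    saturating extracellular signal, either pre-existing (``c_e0 >= 10 K_M``)
    or guaranteed by net accumulation (pi_eff > 0).  Otherwise the sign of
    pi_eff separates quorum (positive) from ratiometric (negative), with the
    latter demoted to indeterminate if transduction is already saturated at
    the intracellular steady state.
    """
    pi_eff = params.pi_eff
    saturating = pi_eff > 0 or c_e0 >= 10.0 * params.K_M
    if params.n >= n_switch and saturating:
        return RegimeLabel(label="chronometric", pi_eff=pi_eff)
    if pi_eff > 0:
        return RegimeLabel(label="quorum", pi_eff=pi_eff)
    if pi_eff < 0:
        if params.f * params.pi > 0 and (params.lambda_i + params.mu) > 0:
            _, ci_star = steady_state_ratiometric(params.with_(lambda_e=0.0))
            if hill_output(ci_star, params) >= saturation_margin * params.O_max:
                return RegimeLabel(label="indeterminate", pi_eff=pi_eff)
        return RegimeLabel(label="ratiometric", pi_eff=pi_eff)
    return RegimeLabel(label="indeterminate", pi_eff=pi_eff)


def delay_time(
    params: ModelParameters,
    threshold: float = 0.5,
    inoculum_od: float = 0.0125,
    horizon: float = 720.0,
    n_points: int = 2000,
) -> float | None:
    """First time the output crosses ``threshold * O_max``, minutes.

    Simulates from a signal-free start and locates the crossing by inverse
    interpolation on a fine grid.  Returns ``None`` (with a warning) if the
    threshold is never crossed within the horizon.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    if threshold == 0:
        return 0.0
    grid = np.linspace(0.0, horizon, n_points)
    nc0 = cells_from_od(inoculum_od, params.V_e)
    init = SignalState(t=0.0, C_i_s=0.0, C_e_s=0.0, C_e_tot=0.0, N_c=nc0)
    traj = simulate(params, init, grid)
    out = np.asarray(hill_output(traj.C_i_s, params))
    target = threshold * params.O_max
    above = np.nonzero(out >= target)[0]
    if len(above) == 0:
        warnings.warn(
            f"output never crossed {threshold:.3g}*O_max within {horizon} min",
            stacklevel=2,
        )
        return None
    i = above[0]
    if i == 0:
        return 0.0
    return float(np.interp(target, out[i - 1 : i + 1], grid[i - 1 : i + 1]))
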