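"""In silico stimulation protocols for the pump-probe FRET reporter.

Each routine mirrors a wet-lab protocol: adding a peptide stimulus (optionally
with a competing peptide) to a cell suspension, assaying the spent supernatant
with fresh reporter cells, following FRET recovery in a growing culture, and
mapping the dose-response relationship between available signaling molecules
per cell and the maximal FRET inhibition.

Protocol timescales are minutes; on that scale growth and degradation are
negligible unless a design enables them (``grow=True``), and extracellular
peptide is stable (lambda_e = 0).  Without growth, degradation, or production
the ODE system reduces to an integrated Michaelis-Menten depletion with the
signal/competitor ratio conserved, which is solved in closed form
(:func:`pumpprobe.model_core.michaelis_depletion`); the general ODE route is
available via ``method="ode"`` and agrees to solver tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import BracketError
from .model_core import (
    ModelParameters,
    N_AVOGADRO,
    SignalState,
    cells_from_od,
    fret_response,
    intracellular_timescale,
    michaelis_depletion,
    simulate,
)

#: Extracellular concentration below which the stimulus counts as depleted.
DEPLETION_THRESHOLD_M = 1e-15
#: Cap on the simulated depletion time (minutes).
DEPLETION_HORIZON_MIN = 24.0 * 60.0


@dataclass(frozen=True)
class StimulationDesign:
    """One stimulation condition.

    ``c_stim``/``c_comp`` are the added signal and competing-peptide
    concentrations (mol/L), ``od`` the cell density, ``v_e`` the medium volume
    (liters), and ``t_s`` the total exposure time in minutes (incubation plus
    the 1-min centrifugation, during which uptake is assumed to continue at
    full rate).  ``grow=True`` enables growth/degradation during exposure.
    """

    c_stim: float
    od: float = 1.6
    c_comp: float = 0.0
    v_e: float = 500e-6
    t_s: float = 6.0
    grow: bool = False

    def __post_init__(self):
        if self.t_s < 1.0:
            raise ValueError("exposure time must include the 1-min spin (t_s >= 1)")
        if min(self.c_stim, self.c_comp, self.od) < 0 or self.v_e <= 0:
            raise ValueError("concentrations and density must be nonnegative, v_e > 0")


@dataclass(frozen=True)
class BioassayDesign:
    """Supernatant bioassay: mix ``v_s`` of supernatant with ``v_cells`` of a
    10x suspension of fresh reporter cells and expose for ``t_b`` minutes.

    ``od_equiv`` is the density of the reconstituted 1x suspension (defaults
    to the stimulation density: a 10x concentrate diluted 1:10 restores 1x).
    The sensitized variant uses v_s = 1950 µL and t_b = 21 min.
    """

    v_s: float = 450e-6
    v_cells: float = 50e-6
    t_b: float = 6.0
    od_equiv: float = 1.6

    def __post_init__(self):
        if self.v_s <= 0 or self.v_cells <= 0:
            raise ValueError("volumes must be positive")
        if self.t_b < 1.0:
            raise ValueError("bioassay exposure must be >= 1 min")


@dataclass(frozen=True)
class DoseResult:
    """Minimal FRET reached at a given signal dose (molecules per cell)."""

    dose: float
    min_fret: float
    c_stim: float
    n_c: float


class StimulationOutcome(NamedTuple):
    fret: float
    c_e_remaining: float  # supernatant signal concentration at t_s, mol/L
    c_i_final: float  # intracellular signal concentration at t_s, mol/L


def _closed_form_exposure(
    c_stim: float, c_comp: float, n_c: float, v_e: float, t: float, params: ModelParameters
) -> tuple[float, float]:
    """(C_e_s, C_i_s) after ``t`` minutes of uptake with no growth/losses.

    Total peptide follows the integrated Michaelis-Menten law; the
    signal:total ratio is invariant because both pools are consumed in
    proportion.  Imported signal is distributed evenly over the cells.
    """
    c_tot0 = c_stim + c_comp
    if c_tot0 == 0.0 or n_c == 0.0:
        return c_stim, 0.0
    rate = n_c * params.v_max / (v_e * N_AVOGADRO)  # mol/(L min)
    c_tot = michaelis_depletion(c_tot0, rate, params.K_M, t)
    ratio = c_stim / c_tot0
    c_e_s = ratio * c_tot
    imported_molar_ext = c_stim - c_e_s  # signal removed from the medium
    c_i = imported_molar_ext * v_e / (n_c * params.V_i)
    return c_e_s, c_i


def simulate_stimulation(
    design: StimulationDesign,
    params: ModelParameters,
    method: str = "auto",
) -> StimulationOutcome:
    """FRET, remaining supernatant signal, and intracellular signal at t_s.

    Cells start signal-free.  With ``grow=False`` (default) growth and
    degradation are frozen (mu = lambda_i = lambda_e = 0) and the closed-form
    depletion solution is used; ``method="ode"`` forces numerical integration.
    """
    n_c = cells_from_od(design.od, design.v_e)
    run_params = params.with_(V_e=design.v_e, pi=0.0, f=0.0, lambda_e=0.0)
    if not design.grow:
        run_params = run_params.with_(mu=0.0, lambda_i=0.0)

    closed_form_ok = (
        run_params.mu == 0.0 and run_params.lambda_i == 0.0 and run_params.lambda_e == 0.0
    )
    if method == "auto":
        method = "closed_form" if closed_form_ok else "ode"
    if method == "closed_form":
        if not closed_form_ok:
            raise ValueError("closed form requires mu = lambda_i = lambda_e = 0")
        c_e_s, c_i = _closed_form_exposure(
            design.c_stim, design.c_comp, n_c, design.v_e, design.t_s, run_params
        )
    elif method == "ode":
        init = SignalState(
            t=0.0,
            C_i_s=0.0,
            C_e_s=design.c_stim,
            C_e_tot=design.c_stim + design.c_comp,
            N_c=n_c,
        )
        grid = np.linspace(0.0, design.t_s, 50)
        traj = simulate(run_params, init, grid)
        c_e_s = float(traj.C_e_s[-1])
        c_i = float(traj.C_i_s[-1])
    else:
        raise ValueError(f"unknown method {method!r}")
    return StimulationOutcome(
        fret=float(fret_response(c_i, params)), c_e_remaining=c_e_s, c_i_final=c_i
    )


def simulate_competition(
    design: StimulationDesign, params: ModelParameters, method: str = "auto"
) -> StimulationOutcome:
    """Stimulation in the presence of a competing peptide.

    Competition enters solely through the shared transporter saturation
    (total peptide in the Michaelis-Menten denominator), so this is the same
    computation as :func:`simulate_stimulation` with the competitor included
    in the initial total; with ``c_comp = 0`` the result is bit-identical.
    """
    return simulate_stimulation(design, params, method=method)


def simulate_bioassay(
    c_supernatant: float,
    design: BioassayDesign,
    params: ModelParameters,
) -> float:
    """FRET of fresh reporter cells exposed to a (diluted) supernatant.

    The supernatant is diluted by v_s/(v_s + v_cells) on mixing with the cell
    concentrate; fresh cells at ``od_equiv`` then take up signal for ``t_b``
    minutes.  Monotone nonincreasing in the supernatant concentration.
    """
    if c_supernatant < 0:
        raise ValueError("supernatant concentration must be nonnegative")
    v_mix = design.v_s + design.v_cells
    c0 = c_supernatant * design.v_s / v_mix
    mix = StimulationDesign(
        c_stim=c0, od=design.od_equiv, v_e=v_mix, t_s=design.t_b
    )
    return simulate_stimulation(mix, params).fret


def simulate_recovery(
    c_stim: float,
    params: ModelParameters,
    horizon: float,
    od: float = 1.6,
    v_e: float = 500e-6,
    n_points: int = 200,
    t_eval: np.ndarray | None = None,
) -> pd.DataFrame:
    """FRET time course of a growing, degrading culture after stimulation.

    The stimulus is depleted within minutes; the intracellular signal then
    relaxes back at the asymptotic rate mu + lambda_i, so FRET recovers
    toward FRET0 with e-folding time ``intracellular_timescale(mu, lambda_i)``.
    Returns a frame with columns t_min, fret, Ci_M, Ce_signal_M, Nc.
    """
    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, n_points)
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval[0] > 0.0:
        grid = np.concatenate([[0.0], t_eval])
        keep = slice(1, None)
    else:
        grid = t_eval
        keep = slice(None)
    n_c = cells_from_od(od, v_e)
    run_params = params.with_(V_e=v_e, pi=0.0, f=0.0)
    init = SignalState(t=0.0, C_i_s=0.0, C_e_s=c_stim, C_e_tot=c_stim, N_c=n_c)
    traj = simulate(run_params, init, grid)
    fret = np.asarray(fret_response(traj.C_i_s, params))
    return pd.DataFrame(
        {
            "t_min": traj.time_grid[keep],
            "fret": fret[keep],
            "Ci_M": traj.C_i_s[keep],
            "Ce_signal_M": traj.C_e_s[keep],
            "Nc": traj.N_c[keep],
        }
    )


def dose_from_condition(c_stim: float, v_e: float, n_c: float) -> float:
    """Signal dose: available signaling molecules per cell."""
    return c_stim * v_e * N_AVOGADRO / n_c


def _min_fret_at_depletion(
    c_stim: float, n_c: float, v_e: float, params: ModelParameters
) -> float:
    """Minimal FRET once the stimulus is (numerically) depleted.

    Runs the no-growth/no-degradation depletion to the threshold
    concentration or the 24-h cap, whichever is first, then maps the
    accumulated intracellular signal through the FRET response.
    """
    if c_stim <= 0.0 or n_c == 0.0:
        return float(params.FRET0)
    rate = n_c * params.v_max / (v_e * N_AVOGADRO)
    c_end = max(DEPLETION_THRESHOLD_M, 0.0)
    if c_end >= c_stim:
        c_end = c_stim
        t_dep = 0.0
    else:
        t_dep = (params.K_M * math.log(c_stim / c_end) + (c_stim - c_end)) / rate
    if t_dep > DEPLETION_HORIZON_MIN:
        c_end = michaelis_depletion(c_stim, rate, params.K_M, DEPLETION_HORIZON_MIN)
    c_i = (c_stim - c_end) * v_e / (n_c * params.V_i)
    return float(fret_response(c_i, params))


def dose_response_surface(
    params: ModelParameters,
    C_grid,
    od_grid,
    v_e: float = 500e-6,
) -> pd.DataFrame:
    """Minimal FRET over a (stimulus concentration x cell density) grid.

    In the no-growth/no-degradation regime the result depends on the two
    factors only through the dose D = C_stim V_e N_A / N_c, so minimal FRET
    is constant along equal-dose contours.
    """
    C_grid = np.atleast_1d(np.asarray(C_grid, dtype=float))
    od_grid = np.atleast_1d(np.asarray(od_grid, dtype=float))
    if C_grid.size == 0 or od_grid.size == 0:
        raise ValueError("grids must be nonempty")
    rows = []
    for c in C_grid:
        for od in od_grid:
            n_c = cells_from_od(od, v_e)
            rows.append(
                (
                    c,
                    od,
                    n_c,
                    dose_from_condition(c, v_e, n_c),
                    _min_fret_at_depletion(c, n_c, v_e, params),
                )
            )
    return pd.DataFrame(
        rows, columns=["c_stim_M", "od", "n_c", "dose", "min_fret"]
    )


def minimal_fret_at_dose(dose: float, params: ModelParameters,
                         od: float = 1.6, v_e: float = 500e-6) -> float:
    """Minimal FRET for a given dose at reference density/volume."""
    n_c = cells_from_od(od, v_e)
    c_stim = dose * n_c / (v_e * N_AVOGADRO)
    return _min_fret_at_depletion(c_stim, n_c, v_e, params)


def dose_response_curve(
    params: ModelParameters,
    dose_grid,
    od: float = 1.6,
    v_e: float = 500e-6,
) -> tuple[pd.DataFrame, float]:
    """Minimal FRET versus dose, and the half-maximal dose D50.

    D50 is the dose at which FRET reaches FRET0 - dFRET/2, located by
    bracketed root-finding on the (monotone) computed curve.  Raises
    :class:`BracketError` if the grid does not span the half-max.
    """
    dose_grid = np.sort(np.asarray(dose_grid, dtype=float))
    fret = np.array([minimal_fret_at_dose(d, params, od, v_e) for d in dose_grid])
    curve = pd.DataFrame({"dose": dose_grid, "min_fret": fret})
    half = params.FRET0 - params.dFRET / 2.0

    def g(log_d):
        return minimal_fret_at_dose(math.exp(log_d), params, od, v_e) - half

    lo, hi = math.log(dose_grid[0]), math.log(dose_grid[-1])
    if g(lo) < 0 or g(hi) > 0:
        raise BracketError("dose grid does not bracket the half-maximal response")
    d50 = math.exp(brentq(g, lo, hi, xtol=1e-12, rtol=1e-12))
    return curve, d50


def signal_integration_uptake(C_e: float, params: ModelParameters) -> float:
    """Molecules imported per cell over the signal-integration time tau.

    N_in = tau * v_max * C_e / (C_e + K_M) with tau = 1/(mu + lambda_i);
    at steady state this estimates the per-cell signal dose.
    """
    if C_e < 0:
        raise ValueError("concentration must be nonnegative")
    tau = intracellular_timescale(params.mu, params.lambda_i)
    if C_e == 0.0:
        return 0.0
    return tau * params.v_max * C_e / (C_e + params.K_M)
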