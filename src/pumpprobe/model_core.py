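"""Core pump-probe model: ODE right-hand side, simulation, and transduction maps.

The model describes a well-mixed population of ``N_c`` cells in an extracellular
volume ``V_e``.  A fraction ``f`` of cells exports a signaling peptide at a
constant per-cell rate ``pi`` (molecules/min).  All cells import peptides
through a single saturable transporter (Michaelis-Menten, maximal per-cell
particle flux ``v_max``, half-saturation ``K_M``); competing peptides share the
transporter, so the saturation denominator uses the *total* extracellular
peptide concentration while the intracellular gain uses only the signal
fraction.  Intracellular signal is diluted by growth (``mu``) and degraded
(``lambda_i``); extracellular peptide may be degraded at ``lambda_e``.

State variables (all molar):
    C_i_s   intracellular signal concentration
    C_e_s   extracellular signal concentration
    C_e_tot total extracellular peptide (signal + competitor)

Internal unit conventions: concentrations in mol/L, volumes in liters, time in
minutes, rates in 1/min; ``v_max`` and ``pi`` are particle fluxes
(molecules/min per cell) converted to molar fluxes with Avogadro's number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .exceptions import (
    GeometryError,
    IntegrationError,
    InvalidStateError,
    NoSteadyStateError,
)

#: Avogadro constant (1/mol), 2019 SI exact value.
N_AVOGADRO = 6.02214076e23

#: Cell-count conversion factor: cells per mL per OD600 unit.
CELLS_PER_ML_PER_OD = 1.19e8

#: Default reporter-cell geometry (µm): rod of length L with hemispherical
#: caps of diameter D, chosen to match the effective cytoplasmic volume of
#: B. subtilis reporter cells grown in minimal medium (~1.1 fL).
DEFAULT_CELL_LENGTH_UM = 2.5
DEFAULT_CELL_DIAMETER_UM = 0.8


def cell_volume(length_um: float, diameter_um: float) -> float:
    """Volume (liters) of a rod-shaped cell: cylinder with hemispherical caps.

    V = pi (L - D) (D/2)^2 + 4/3 pi (D/2)^3, with L, D in micrometers.
    """
    if diameter_um <= 0 or length_um < diameter_um:
        raise GeometryError(
            f"need L >= D > 0, got L={length_um} um, D={diameter_um} um"
        )
    r = diameter_um / 2.0
    v_um3 = math.pi * (length_um - diameter_um) * r**2 + (4.0 / 3.0) * math.pi * r**3
    return v_um3 * 1e-15  # 1 um^3 = 1e-15 L


def cells_from_od(od: float, V_e: float, alpha: float = CELLS_PER_ML_PER_OD) -> float:
    """Number of cells at optical density ``od`` in volume ``V_e`` (liters).

    ``alpha`` is the counting calibration in cells/mL per OD600 unit.
    """
    if od < 0:
        raise ValueError(f"optical density must be nonnegative, got {od}")
    if V_e <= 0:
        raise ValueError(f"volume must be positive, got {V_e}")
    return od * alpha * (V_e * 1e3)


def intracellular_timescale(mu: float, lambda_i: float) -> float:
    """Characteristic signal-processing time tau = 1/(mu + lambda_i), minutes.

    Returns ``inf`` when both loss rates vanish (signal is never cleared).
    """
    total = mu + lambda_i
    if total < 0:
        raise ValueError("loss rates must be nonnegative")
    if total == 0:
        return math.inf
    return 1.0 / total


@dataclass(frozen=True)
class ModelParameters:
    """All kinetic and transduction constants of the pump-probe model.

    Attributes
    ----------
    v_max : float
        Maximal per-cell import flux, molecules/min.
    K_M : float
        Transport half-saturation constant, mol/L.
    pi : float
        Per-producer-cell signal production rate, molecules/min.
    f : float
        Fraction of producer cells, in [0, 1].
    lambda_e, lambda_i, mu : float
        Extracellular degradation, intracellular degradation, and growth
        (dilution) rates, 1/min.
    V_e, V_i : float
        Extracellular and single-cell volumes, liters.
    EC50 : float
        Intracellular concentration for half-maximal transduction, mol/L.
    n : float
        Hill coefficient of transduction.
    O_max : float
        Maximal output of the Hill response (dimensionless).
    FRET0 : float
        FRET efficiency of unstimulated cells (fraction).
    dFRET : float
        Maximal FRET drop at saturating intracellular signal (fraction).
    """

    v_max: float = 1.9e5
    K_M: float = 140e-9
    pi: float = 0.0
    f: float = 0.0
    lambda_e: float = 0.0
    lambda_i: float = 0.0
    mu: float = 0.0
    V_e: float = 500e-6
    V_i: float = field(
        default_factory=lambda: cell_volume(
            DEFAULT_CELL_LENGTH_UM, DEFAULT_CELL_DIAMETER_UM
        )
    )
    EC50: float = 38e-6
    n: float = 1.4
    O_max: float = 1.0
    FRET0: float = 0.110
    dFRET: float = 0.064

    def __post_init__(self):
        for name in ("v_max", "pi", "lambda_e", "lambda_i", "mu", "O_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("K_M", "V_e", "V_i", "EC50", "n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")
        if not 0.0 <= self.dFRET <= self.FRET0 <= 1.0:
            raise ValueError("need 0 <= dFRET <= FRET0 <= 1")

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @property
    def pi_eff(self) -> float:
        """Effective net production rate f*pi - v_max (molecules/min)."""
        return self.f * self.pi - self.v_max

    @property
    def molecules_per_molar(self) -> float:
        """Molecules per cell corresponding to 1 mol/L intracellular."""
        return self.V_i * N_AVOGADRO


def phra_best_fit(**overrides) -> ModelParameters:
    """Best-fit parameters of the PhrA-RapA-Spo0F reporter system.

    Growth and degradation default to zero (short stimulation protocols);
    pass ``mu``/``lambda_i`` explicitly for growing-culture scenarios
    (measured growth rate 0.58/h; fitted intracellular degradation 0.63/h).
    """
    defaults = dict(
        v_max=1.9e5,
        K_M=140e-9,
        EC50=38e-6,
        n=1.4,
        FRET0=0.110,
        dFRET=0.064,
    )
    defaults.update(overrides)
    return ModelParameters(**defaults)


@dataclass(frozen=True)
class SignalState:
    """Instantaneous model state.

    ``t`` minutes; concentrations in mol/L; ``N_c`` in cells.  ``C_e_tot`` is
    the total extracellular peptide (signal plus competitor) and must not be
    smaller than the signal fraction ``C_e_s``.
    """

    t: float
    C_i_s: float
    C_e_s: float
    C_e_tot: float
    N_c: float

    def __post_init__(self):
        if min(self.C_i_s, self.C_e_s, self.C_e_tot, self.N_c) < 0:
            raise InvalidStateError(f"negative quantity in state {self}")
        # tolerate roundoff at the 1e-12 relative level
        if self.C_e_tot < self.C_e_s * (1 - 1e-12) - 1e-30:
            raise InvalidStateError("C_e_tot must be >= C_e_s")

    @property
    def C_e_other(self) -> float:
        """Competing (non-signal) extracellular peptide concentration."""
        return max(self.C_e_tot - self.C_e_s, 0.0)


def ode_rhs(state: SignalState, params: ModelParameters) -> tuple[float, float, float]:
    """Time derivatives (dC_i_s/dt, dC_e_s/dt, dC_e_tot/dt) in mol/(L min).

    Import follows Michaelis-Menten kinetics with substrate competition: the
    shared saturation denominator uses the total peptide concentration, while
    only the signal fraction contributes to the intracellular gain.
    """
    p = params
    denom = p.K_M + state.C_e_tot
    uptake_s = p.v_max * state.C_e_s / denom          # molecules/min per cell
    uptake_tot = p.v_max * state.C_e_tot / denom
    dCi = uptake_s / (p.V_i * N_AVOGADRO) - (p.lambda_i + p.mu) * state.C_i_s
    production = p.pi * p.f * state.N_c / (p.V_e * N_AVOGADRO)
    dCes = production - state.N_c * uptake_s / (p.V_e * N_AVOGADRO) - p.lambda_e * state.C_e_s
    dCet = production - state.N_c * uptake_tot / (p.V_e * N_AVOGADRO) - p.lambda_e * state.C_e_tot
    return dCi, dCes, dCet


@dataclass
class Trajectory:
    """Solution of the pump-probe ODEs on a time grid.

    Arrays are aligned with ``time_grid`` (minutes).  ``params`` records the
    parameter set used, including the cell volume, for provenance.
    """

    time_grid: np.ndarray
    C_i_s: np.ndarray
    C_e_s: np.ndarray
    C_e_tot: np.ndarray
    N_c: np.ndarray
    params: ModelParameters

    def state_at(self, i: int) -> SignalState:
        return SignalState(
            t=float(self.time_grid[i]),
            C_i_s=float(self.C_i_s[i]),
            C_e_s=float(self.C_e_s[i]),
            C_e_tot=float(max(self.C_e_tot[i], self.C_e_s[i])),
            N_c=float(self.N_c[i]),
        )

    @property
    def states(self) -> list[SignalState]:
        return [self.state_at(i) for i in range(len(self.time_grid))]

    def total_signal_molecules(self) -> np.ndarray:
        """N_A (V_e C_e_s + N_c V_i C_i_s): conserved when all gains/losses vanish."""
        p = self.params
        return N_AVOGADRO * (p.V_e * self.C_e_s + self.N_c * p.V_i * self.C_i_s)

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_min": self.time_grid,
                "Ci_M": self.C_i_s,
                "Ce_signal_M": self.C_e_s,
                "Ce_total_M": self.C_e_tot,
                "Nc": self.N_c,
            }
        )


def simulate(
    params: ModelParameters,
    init: SignalState,
    time_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-15,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the pump-probe ODEs on ``time_grid`` (strictly increasing, min).

    Population growth enters analytically as N_c(t) = N_c(0) exp(mu t) rather
    than as a state variable.  States are clipped at zero after the solve to
    absorb solver roundoff.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be strictly increasing with >= 2 points")
    if not math.isclose(t[0], init.t, rel_tol=0, abs_tol=1e-9):
        raise ValueError("time_grid must start at init.t")

    p = params
    nc0 = init.N_c
    t0 = init.t

    def rhs(ti, y):
        ci, ces, cet = y
        ces = max(ces, 0.0)
        cet = max(cet, ces)
        ci = max(ci, 0.0)
        nc = nc0 * math.exp(p.mu * (ti - t0))
        denom = p.K_M + cet
        uptake_s = p.v_max * ces / denom
        uptake_tot = p.v_max * cet / denom
        production = p.pi * p.f * nc / (p.V_e * N_AVOGADRO)
        dci = uptake_s / (p.V_i * N_AVOGADRO) - (p.lambda_i + p.mu) * ci
        dces = production - nc * uptake_s / (p.V_e * N_AVOGADRO) - p.lambda_e * ces
        dcet = production - nc * uptake_tot / (p.V_e * N_AVOGADRO) - p.lambda_e * cet
        return (dci, dces, dcet)

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        [init.C_i_s, init.C_e_s, init.C_e_tot],
        t_eval=t,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if len(sol.t) else float(t[0])
        raise IntegrationError(f"ODE solver failed: {sol.message}", last_t=last)
    y = np.clip(sol.y, 0.0, None)
    nc = nc0 * np.exp(p.mu * (t - t0))
    return Trajectory(
        time_grid=t,
        C_i_s=y[0],
        C_e_s=y[1],
        C_e_tot=np.maximum(y[2], y[1]),
        N_c=nc,
        params=params,
    )


def hill_output(C_i, params: ModelParameters):
    """Transduction output O = O_max C_i^n / (EC50^n + C_i^n); vectorized."""
    ci = np.asarray(C_i, dtype=float)
    if np.any(ci < 0):
        raise ValueError("intracellular concentration must be nonnegative")
    x = (ci / params.EC50) ** params.n
    out = params.O_max * x / (1.0 + x)
    return out if out.ndim else float(out)


def fret_response(C_i, params: ModelParameters):
    """FRET efficiency FRET0 - dFRET * C_i^n / (EC50^n + C_i^n); vectorized.

    Monotone nonincreasing in C_i, ranging from FRET0 (unstimulated) down to
    FRET0 - dFRET at saturating intracellular signal.
    """
    ci = np.asarray(C_i, dtype=float)
    if np.any(ci < 0):
        raise ValueError("intracellular concentration must be nonnegative")
    x = (ci / params.EC50) ** params.n
    out = params.FRET0 - params.dFRET * x / (1.0 + x)
    return out if out.ndim else float(out)


def steady_state_ratiometric(params: ModelParameters) -> tuple[float, float]:
    """Extracellular and intracellular steady state in the ratiometric regime.

    Requires no extracellular degradation and uptake capacity exceeding
    production (f pi < v_max).  The extracellular fixed point balances
    per-cell production against per-cell uptake and is independent of N_c:

        C_e* = K_M f pi / (v_max - f pi)

    The intracellular fixed point balances import against loss:

        C_i* = v_max C_e* / ((K_M + C_e*) V_i N_A (lambda_i + mu))
    """
    p = params
    if p.lambda_e != 0:
        raise ValueError("ratiometric steady state assumes lambda_e = 0")
    net = p.f * p.pi
    if net >= p.v_max:
        raise NoSteadyStateError(
            f"f*pi = {net:.3g} >= v_max = {p.v_max:.3g}: net production is "
            "positive (quorum regime), no extracellular steady state"
        )
    ce = p.K_M * net / (p.v_max - net)
    loss = p.lambda_i + p.mu
    if ce == 0.0:
        return 0.0, 0.0
    if loss == 0.0:
        return ce, math.inf
    ci = p.v_max * ce / ((p.K_M + ce) * p.V_i * N_AVOGADRO * loss)
    return ce, ci


def michaelis_depletion(C0: float, rate: float, K_M: float, t) -> np.ndarray | float:
    """Concentration after Michaelis-Menten consumption: dC/dt = -rate C/(K_M + C).

    Closed-form implicit solution of the integrated rate law

        K_M ln(C0/C) + (C0 - C) = rate * t

    solved for C by bracketed root-finding (the left side is strictly
    decreasing in C).  ``rate`` is the maximal volumetric consumption rate in
    mol/(L min); scalar or array ``t`` in minutes.
    """
    if C0 < 0 or rate < 0 or K_M <= 0:
        raise ValueError("need C0 >= 0, rate >= 0, K_M > 0")

    def solve_one(ti: float) -> float:
        if ti < 0:
            raise ValueError("time must be nonnegative")
        if C0 == 0.0 or rate == 0.0 or ti == 0.0:
            return C0
        budget = rate * ti
        # solve in log-concentration: u = ln C keeps the bracket well scaled
        # even when the pool is depleted far below floating-point epsilon
        log_c0 = math.log(C0)

        def g(u):
            return K_M * (log_c0 - u) + (C0 - math.exp(u)) - budget

        u_hi = log_c0  # g(u_hi) = -budget < 0
        u_lo = log_c0 - (budget + C0) / K_M  # g(u_lo) >= C0 > 0 analytically
        if g(u_hi) >= 0.0:
            return C0
        if g(u_lo) <= 0.0:
            # rounding swallowed the bracket: the pool is depleted to the
            # log-dominated bound itself
            return math.exp(u_lo)
        u = brentq(g, u_lo, u_hi, xtol=1e-12, maxiter=300)
        return math.exp(u)

    t_arr = np.asarray(t, dtype=float)
    if t_arr.ndim == 0:
        return solve_one(float(t_arr))
    return np.array([solve_one(ti) for ti in t_arr])
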