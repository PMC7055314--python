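"""Parameter inference for the pump-probe model.

Fitting follows a two-stage procedure: the kinetic and transduction
parameters (v_max, K_M, EC50, FRET0, dFRET, n) are estimated jointly by
minimizing the plain sum of squared residuals (SSR) over all short-protocol
datasets with growth and degradation frozen; the intracellular degradation
rate lambda_i is then determined separately from a FRET-recovery time course
in a growing culture, with the stage-one estimates held fixed.

Confidence intervals come from the F-statistic profile constraint

    (SSR(theta) - SSR(theta_hat)) / SSR(theta_hat) <= p/(n-p) * F_{p,n-p}^alpha

profiled one parameter at a time (the remaining parameters re-optimized), and
from case-resampling bootstrap bands over predicted curves.

Positive scale parameters (v_max, K_M, EC50, lambda_i) are optimized on a
log10 scale; FRET0, dFRET, n on a linear scale.  Residuals are unweighted,
and the data enter as condition-level means.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq, least_squares, minimize_scalar
from scipy.stats import qmc

from .exceptions import FitFailureError
from .model_core import ModelParameters
from .protocols import (
    BioassayDesign,
    StimulationDesign,
    minimal_fret_at_dose,
    simulate_bioassay,
    simulate_recovery,
    simulate_stimulation,
)

# ---------------------------------------------------------------------------
# Observation designs and datasets


@dataclass(frozen=True)
class SupernatantAssay:
    """Bioassay readout of the supernatant produced by a stimulation."""

    stim: StimulationDesign
    bio: BioassayDesign


@dataclass(frozen=True)
class RecoveryDesign:
    """One time point of a FRET-recovery experiment in a growing culture.

    ``mu`` is the independently measured growth rate (1/min); the
    intracellular degradation rate comes from the parameter set under test.
    """

    t: float
    c_stim: float = 10e-9
    od: float = 1.6
    v_e: float = 500e-6
    mu: float = 0.58 / 60.0


@dataclass(frozen=True)
class DoseResponseDesign:
    """Minimal-FRET readout at a given signal dose (molecules per cell)."""

    dose: float
    od: float = 1.6
    v_e: float = 500e-6


Design = object  # union of the design types above plus StimulationDesign


@dataclass(frozen=True)
class Observation:
    design: Design
    fret_mean: float
    fret_sd: float = 0.0
    n_e: int = 1

    def __post_init__(self):
        if not 0.0 <= self.fret_mean <= 1.0:
            raise ValueError("fret_mean must lie in [0, 1]")
        if self.fret_sd < 0 or self.n_e < 1:
            raise ValueError("need fret_sd >= 0 and n_e >= 1")


@dataclass
class ExperimentDataset:
    """A set of FRET observations sharing a protocol design family."""

    observations: list[Observation]
    tag: str = ""

    def __len__(self):
        return len(self.observations)


def dataset_predictions(params: ModelParameters, dataset: ExperimentDataset) -> np.ndarray:
    """Model-predicted FRET for every observation in ``dataset``."""
    obs = dataset.observations
    preds = np.empty(len(obs))
    recovery_groups: dict = defaultdict(list)
    for i, ob in enumerate(obs):
        d = ob.design
        try:
            if isinstance(d, StimulationDesign):
                preds[i] = simulate_stimulation(d, params).fret
            elif isinstance(d, SupernatantAssay):
                out = simulate_stimulation(d.stim, params)
                preds[i] = simulate_bioassay(out.c_e_remaining, d.bio, params)
            elif isinstance(d, DoseResponseDesign):
                preds[i] = minimal_fret_at_dose(d.dose, params, d.od, d.v_e)
            elif isinstance(d, RecoveryDesign):
                recovery_groups[(d.c_stim, d.od, d.v_e, d.mu)].append((i, d.t))
            else:
                raise TypeError(f"unknown design type {type(d).__name__}")
        except TypeError:
            raise
        except Exception as err:
            raise RuntimeError(
                f"simulation failed for observation {i} of dataset "
                f"{dataset.tag!r} ({d})"
            ) from err
    for (c_stim, od, v_e, mu), items in recovery_groups.items():
        idx = np.array([i for i, _ in items])
        times = np.array([t for _, t in items])
        uniq, inverse = np.unique(times, return_inverse=True)
        run = params.with_(mu=mu)
        t_eval = uniq if len(uniq) > 1 else np.array([0.0, max(uniq[0], 1.0)])
        frame = simulate_recovery(
            c_stim, run, horizon=float(t_eval[-1]), od=od, v_e=v_e, t_eval=t_eval
        )
        fr = frame["fret"].to_numpy()
        if len(uniq) == 1:
            fr = fr[:1] if uniq[0] == 0.0 else fr[-1:]
        preds[idx] = fr[inverse]
    return preds


def predictions(params: ModelParameters, datasets: Sequence[ExperimentDataset]) -> np.ndarray:
    return np.concatenate([dataset_predictions(params, ds) for ds in datasets])


def residuals(params: ModelParameters, datasets: Sequence[ExperimentDataset]) -> np.ndarray:
    means = np.concatenate(
        [[ob.fret_mean for ob in ds.observations] for ds in datasets]
    )
    return predictions(params, datasets) - means


def sum_squared_residuals(
    params: ModelParameters, datasets: Sequence[ExperimentDataset]
) -> float:
    """Plain (unweighted) SSR of all datasets under ``params``."""
    r = residuals(params, datasets)
    return float(r @ r)


# ---------------------------------------------------------------------------
# Parameterization of the fit

GLOBAL_FIT_PARAMS = ("v_max", "K_M", "EC50", "FRET0", "dFRET", "n")
LOG_SCALE_PARAMS = frozenset({"v_max", "K_M", "EC50", "lambda_i"})

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "v_max": (1e3, 1e8),
    "K_M": (1e-10, 1e-4),
    "EC50": (1e-7, 1e-2),
    "FRET0": (0.0, 1.0),
    "dFRET": (0.0, 1.0),
    "n": (0.5, 5.0),
    "lambda_i": (0.0, 0.2),
}


def _to_internal(name: str, value: float) -> float:
    return math.log10(value) if name in LOG_SCALE_PARAMS else value


def _from_internal(name: str, x: float) -> float:
    return 10.0**x if name in LOG_SCALE_PARAMS else x


def _internal_bounds(names, bounds):
    lo, hi = [], []
    for name in names:
        b = bounds[name]
        if name in LOG_SCALE_PARAMS:
            lo.append(math.log10(max(b[0], 1e-300)))
            hi.append(math.log10(b[1]))
        else:
            lo.append(b[0])
            hi.append(b[1])
    return np.array(lo), np.array(hi)


def _apply(template: ModelParameters, names, x) -> ModelParameters:
    updates = {name: _from_internal(name, xi) for name, xi in zip(names, x)}
    if "FRET0" in updates or "dFRET" in updates:
        # keep the record invariant 0 <= dFRET <= FRET0 <= 1 during search
        f0 = updates.get("FRET0", template.FRET0)
        df = updates.get("dFRET", template.dFRET)
        updates["dFRET"] = min(df, f0)
        updates["FRET0"] = f0
    return template.with_(**updates)


@dataclass
class FitResult:
    """Outcome of an SSR fit, with provenance for reproducibility."""

    theta_hat: dict[str, float]
    params: ModelParameters
    ssr: float
    n_points: int
    p: int
    free: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    seed: int | None = None
    n_starts: int = 1
    n_converged: int = 1
    ci: dict[str, tuple[float, float]] | None = None
    bootstrap_bands: dict | None = None

    def __post_init__(self):
        if self.ssr < 0:
            raise ValueError("ssr must be nonnegative")


def fit_global(
    datasets: Sequence[ExperimentDataset],
    template: ModelParameters | None = None,
    free: Sequence[str] = GLOBAL_FIT_PARAMS,
    theta0: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 16,
    seed: int = 0,
) -> FitResult:
    """Stage-one global fit: minimize the SSR over all datasets.

    Growth and intracellular degradation are frozen at zero in this stage
    (``lambda_i`` is fitted separately from recovery data).  A damped
    least-squares optimizer is run from ``n_starts`` Latin-hypercube starting
    points within the bounds (plus ``theta0`` if supplied) and the lowest-SSR
    converged solution is returned.
    """
    if template is None:
        template = ModelParameters()
    template = template.with_(lambda_i=0.0, mu=0.0)
    free = tuple(free)
    all_bounds = dict(DEFAULT_BOUNDS)
    if bounds:
        all_bounds.update(bounds)
    lo, hi = _internal_bounds(free, all_bounds)

    tags = {ds.tag for ds in datasets}
    has_time_course = any("activation" in t or "recovery" in t or "time" in t for t in tags)
    has_dose = any("dose" in t or "competition" in t for t in tags)
    if len(tags) > 1 and not (has_time_course and has_dose):
        warnings.warn(
            "datasets do not appear to cover both time-course and dose-series "
            "designs; parameters may be poorly identifiable",
            stacklevel=2,
        )

    means = np.concatenate(
        [[ob.fret_mean for ob in ds.observations] for ds in datasets]
    )

    def resid_x(x):
        params = _apply(template, free, x)
        return predictions(params, datasets) - means

    starts = []
    if theta0 is not None:
        starts.append(np.array([_to_internal(k, theta0[k]) for k in free]))
    n_lhs = max(n_starts - len(starts), 0)
    if n_lhs:
        sampler = qmc.LatinHypercube(d=len(free), seed=seed)
        pts = sampler.random(n_lhs)
        # keep starts strictly interior to avoid zero-gradient edges
        starts.extend(lo + (0.05 + 0.9 * pts) * (hi - lo))

    best = None
    n_conv = 0
    for x0 in starts:
        try:
            sol = least_squares(
                resid_x, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if not sol.success:
            continue
        n_conv += 1
        ssr = float(2.0 * sol.cost)
        if best is None or ssr < best[0]:
            best = (ssr, sol.x)
    if best is None:
        raise FitFailureError(
            f"no optimization start converged ({len(starts)} starts attempted)"
        )
    ssr, x_hat = best
    params_hat = _apply(template, free, x_hat)
    theta_hat = {k: getattr(params_hat, k) for k in free}
    return FitResult(
        theta_hat=theta_hat,
        params=params_hat,
        ssr=ssr,
        n_points=len(means),
        p=len(free),
        free=free,
        bounds={k: all_bounds[k] for k in free},
        seed=seed,
        n_starts=len(starts),
        n_converged=n_conv,
    )


def fit_lambda_i(
    recovery_dataset: ExperimentDataset,
    fitted: FitResult | ModelParameters,
    bounds: tuple[float, float] = (0.0, 0.2),
) -> tuple[float, float]:
    """Stage-two fit of the intracellular degradation rate (1/min).

    One-dimensional SSR minimization over lambda_i with all other parameters
    frozen at the stage-one estimates; the growth rate is taken from each
    recovery design (measured independently).  Returns (lambda_i_hat, ssr).
    """
    params = fitted.params if isinstance(fitted, FitResult) else fitted

    def ssr_of(lam: float) -> float:
        return sum_squared_residuals(params.with_(lambda_i=lam), [recovery_dataset])

    probe = np.linspace(bounds[0], bounds[1], 5)
    vals = [ssr_of(v) for v in probe]
    if max(vals) - min(vals) <= 1e-14 * max(1.0, max(vals)):
        warnings.warn("SSR profile over lambda_i is flat: unidentifiable", stacklevel=2)

    sol = minimize_scalar(
        ssr_of, bounds=bounds, method="bounded", options={"xatol": 1e-8}
    )
    return float(sol.x), float(sol.fun)


def staged_fit(
    global_datasets: Sequence[ExperimentDataset],
    recovery_dataset: ExperimentDataset | None = None,
    template: ModelParameters | None = None,
    n_starts: int = 16,
    seed: int = 0,
    **kwargs,
) -> FitResult:
    """Global fit followed by the one-dimensional lambda_i fit."""
    fit = fit_global(
        global_datasets, template=template, n_starts=n_starts, seed=seed, **kwargs
    )
    if recovery_dataset is not None:
        lam, ssr_rec = fit_lambda_i(recovery_dataset, fit)
        fit.theta_hat["lambda_i"] = lam
        fit.params = fit.params.with_(lambda_i=lam)
        fit.ssr += ssr_rec
        fit.n_points += len(recovery_dataset)
        fit.p += 1
        fit.free = fit.free + ("lambda_i",)
        fit.bounds["lambda_i"] = DEFAULT_BOUNDS["lambda_i"]
    return fit


# ---------------------------------------------------------------------------
# Profile-likelihood confidence intervals


def f_constraint_threshold(ssr_hat: float, p: int, n: int, alpha: float) -> float:
    """SSR ceiling of the F-statistic confidence region at level 1-alpha."""
    if n <= p:
        raise ValueError("need more data points than parameters")
    return ssr_hat * (1.0 + p / (n - p) * stats.f.ppf(1.0 - alpha, p, n - p))


def profile_interval(
    resid_fn: Callable[[np.ndarray], np.ndarray],
    x_hat: np.ndarray,
    k: int,
    threshold: float,
    lower: np.ndarray,
    upper: np.ndarray,
    rtol: float = 1e-8,
) -> tuple[float, float]:
    """Profile-likelihood bounds for component ``k`` of an internal vector.

    For each trial value of x[k] the remaining components are re-optimized by
    damped least squares; the bound is where the profiled SSR crosses
    ``threshold``.  Returns +/-inf (with a warning) for a side whose profile
    stays below the threshold all the way to its box bound.
    """
    x_hat = np.asarray(x_hat, dtype=float)
    others = [j for j in range(len(x_hat)) if j != k]

    def profiled_ssr(v: float, warm: np.ndarray) -> tuple[float, np.ndarray]:
        if not others:
            x = x_hat.copy()
            x[k] = v
            r = resid_fn(x)
            return float(r @ r), x
        x0 = warm[others]

        def rfun(xo):
            x = x_hat.copy()
            x[k] = v
            x[others] = xo
            return resid_fn(x)

        sol = least_squares(
            rfun, np.clip(x0, lower[others], upper[others]),
            bounds=(lower[others], upper[others]), method="trf",
            xtol=1e-12, ftol=1e-12,
        )
        x_full = x_hat.copy()
        x_full[k] = v
        x_full[others] = sol.x
        return float(2.0 * sol.cost), x_full

    span = upper[k] - lower[k]
    results = []
    for direction, limit in ((-1.0, lower[k]), (+1.0, upper[k])):
        warm = x_hat.copy()
        step = max(abs(x_hat[k]) * 0.02, span * 1e-3, 1e-8)
        v_in, ssr_in, x_in = x_hat[k], 0.0, x_hat.copy()
        v_out = None
        while True:
            v = x_hat[k] + direction * step
            if (direction < 0 and v <= limit) or (direction > 0 and v >= limit):
                v = limit
            ssr_v, warm = profiled_ssr(v, warm)
            if ssr_v > threshold:
                v_out, ssr_out = v, ssr_v
                break
            v_in, ssr_in, x_in = v, ssr_v, warm.copy()
            if v == limit:
                break
            step *= 2.0
        if v_out is None:
            warnings.warn(
                f"profile for component {k} stays below the threshold up to "
                f"its bound; interval is open on that side", stacklevel=2,
            )
            results.append(-math.inf if direction < 0 else math.inf)
            continue

        # refine within the bracket, warm-starting each inner re-optimization
        # from the nearest previously profiled solution
        warm_state = [x_in.copy()]

        def g(v):
            ssr_v, x_v = profiled_ssr(v, warm_state[0])
            warm_state[0] = x_v
            return ssr_v - threshold

        a, b = (v_in, v_out) if v_in < v_out else (v_out, v_in)
        fa = ssr_in - threshold if a == v_in else ssr_out - threshold
        fb = ssr_out - threshold if b == v_out else ssr_in - threshold
        if fa * fb > 0:
            # inner-optimizer jitter collapsed the bracket; report the last
            # value known to satisfy the constraint (conservative)
            results.append(float(v_in))
            continue
        root = brentq(g, a, b, xtol=max(abs(x_hat[k]), 1.0) * rtol)
        results.append(float(root))
    return results[0], results[1]


def profile_confidence_interval(
    fit: FitResult,
    datasets: Sequence[ExperimentDataset],
    alpha: float = 0.05,
    which: Sequence[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """F-constraint profile confidence intervals for the fitted parameters.

    ``datasets`` must be the datasets the fit was computed from (excluding
    ``lambda_i``-stage data, the stage-one datasets).  With zero residual
    error the intervals collapse to the point estimate.
    """
    free = [k for k in fit.free if k != "lambda_i"]
    if which is not None:
        which = list(which)
        unknown = set(which) - set(free)
        if unknown:
            raise ValueError(f"not fitted parameters: {sorted(unknown)}")
    else:
        which = free
    n = sum(len(ds) for ds in datasets)
    p = len(free)
    if fit.ssr <= 1e-18:
        return {k: (fit.theta_hat[k], fit.theta_hat[k]) for k in which}
    ssr_hat = sum_squared_residuals(fit.params, datasets)
    threshold = f_constraint_threshold(ssr_hat, p, n, alpha)

    template = fit.params
    means = np.concatenate(
        [[ob.fret_mean for ob in ds.observations] for ds in datasets]
    )

    def resid_fn(x):
        return predictions(_apply(template, free, x), datasets) - means

    lo_b, hi_b = _internal_bounds(free, fit.bounds)
    x_hat = np.array([_to_internal(k, fit.theta_hat[k]) for k in free])
    out = {}
    for name in which:
        k = free.index(name)
        lo, hi = profile_interval(resid_fn, x_hat, k, threshold, lo_b, hi_b)
        out[name] = (
            _from_internal(name, lo) if math.isfinite(lo) else lo,
            _from_internal(name, hi) if math.isfinite(hi) else hi,
        )
    fit.ci = {**(fit.ci or {}), **out}
    return out


# ---------------------------------------------------------------------------
# Bootstrap confidence bands


def bootstrap_curves(
    datasets: Sequence[ExperimentDataset],
    fit: FitResult,
    B: int = 1000,
    seed: int = 0,
    quantiles: tuple[float, float] = (0.025, 0.975),
    max_failure_fraction: float = 0.2,
) -> dict[str, np.ndarray]:
    """Case-resampling bootstrap bands of the fitted curves.

    Observations are resampled with replacement within each dataset, the
    stage-one fit is repeated from the full-data optimum, and the predicted
    value at every original observation is recorded; returns per-dataset
    arrays of shape (2, n_obs) holding the lower and upper quantiles.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = np.random.default_rng(seed)
    free = [k for k in fit.free if k != "lambda_i"]
    template = fit.params.with_(lambda_i=0.0, mu=0.0)
    lo_b, hi_b = _internal_bounds(free, fit.bounds)
    x_hat = np.array([_to_internal(k, fit.theta_hat[k]) for k in free])

    n_obs = [len(ds) for ds in datasets]
    all_preds: list[np.ndarray] = []
    failures = 0
    for _ in range(B):
        resampled = []
        for ds in datasets:
            idx = rng.integers(0, len(ds), size=len(ds))
            resampled.append(
                ExperimentDataset(
                    observations=[ds.observations[i] for i in idx], tag=ds.tag
                )
            )
        means = np.concatenate(
            [[ob.fret_mean for ob in ds.observations] for ds in resampled]
        )

        def resid_x(x):
            return predictions(_apply(template, free, x), resampled) - means

        try:
            sol = least_squares(
                resid_x, x_hat, bounds=(lo_b, hi_b), method="trf",
                xtol=1e-10, ftol=1e-10,
            )
            if not sol.success:
                raise RuntimeError(sol.message)
        except Exception:
            failures += 1
            continue
        params_b = _apply(template, free, sol.x)
        all_preds.append(predictions(params_b, datasets))
    if failures > max_failure_fraction * B:
        raise FitFailureError(
            f"{failures}/{B} bootstrap refits failed (limit "
            f"{max_failure_fraction:.0%})"
        )
    stacked = np.vstack(all_preds)
    qlo, qhi = np.quantile(stacked, quantiles, axis=0)
    bands: dict[str, np.ndarray] = {}
    start = 0
    for ds, m in zip(datasets, n_obs):
        bands[ds.tag] = np.vstack([qlo[start : start + m], qhi[start : start + m]])
        start += m
    fit.bootstrap_bands = bands
    return bands
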