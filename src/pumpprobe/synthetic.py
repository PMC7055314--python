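"""Synthetic-data generators emulating every measurement the pipeline consumes.

Each generator is the exact inverse of its quantifier at zero noise, so the
round trip generator -> quantifier recovers the generating truth; with noise
enabled the statistical structure matches the analysis assumptions (Gaussian
replicate scatter on the FRET scale, Poisson photon counting on bleach
traces, multiplicative intensity noise on single-cell channels, exponential
growth with multiplicative OD noise).  All generators are deterministic under
a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .fret_quant import BleachTrace, EFretCalibration, SingleCellIntensities
from .inference import (
    ExperimentDataset,
    Observation,
    dataset_predictions,
)
from .model_core import ModelParameters


@dataclass(frozen=True)
class NoiseSpec:
    """Noise magnitudes for the generators.

    ``fret_sd`` is the replicate standard deviation on the FRET scale
    (default 0.006, matching the ~0.6-percentage-point scatter of population
    FRET measurements); ``trace_noise`` selects Poisson photon counting
    (default for photomultiplier traces) or Gaussian; ``intensity_cv`` is the
    per-channel coefficient of variation of single-cell intensities.
    """

    fret_sd: float = 0.006
    trace_noise: str = "poisson"
    trace_gauss_sd: float = 0.0
    intensity_cv: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if min(self.fret_sd, self.trace_gauss_sd, self.intensity_cv) < 0:
            raise ValueError("noise scales must be nonnegative")
        if self.trace_noise not in ("poisson", "gaussian", "none"):
            raise ValueError("trace_noise must be poisson, gaussian or none")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_seed(self, seed: int) -> "NoiseSpec":
        return replace(self, seed=seed)


def gen_fret_dataset(
    params: ModelParameters,
    design_suite: list[tuple[str, list, int]],
    noise: NoiseSpec,
) -> list[ExperimentDataset]:
    """Model-true FRET plus Gaussian replicate noise for a suite of designs.

    ``design_suite`` is a list of (tag, designs, n_e) panels.  For each
    condition, ``n_e`` replicates are drawn as truth + N(0, fret_sd) and the
    replicate mean and sample SD are reported, as in the population assays.
    """
    rng = noise.rng()
    datasets = []
    for tag, designs, n_e in design_suite:
        truth = dataset_predictions(
            params, ExperimentDataset([Observation(d, 0.0) for d in designs], tag)
        )
        observations = []
        for d, f_true in zip(designs, truth):
            if noise.fret_sd == 0.0:
                mean, sd = float(f_true), 0.0
            else:
                reps = f_true + rng.normal(0.0, noise.fret_sd, size=n_e)
                reps = np.clip(reps, 0.0, 1.0)
                mean = float(np.clip(np.mean(reps), 0.0, 1.0))
                sd = float(np.std(reps, ddof=1)) if n_e > 1 else 0.0
            observations.append(
                Observation(design=d, fret_mean=mean, fret_sd=sd, n_e=n_e)
            )
        datasets.append(ExperimentDataset(observations=observations, tag=tag))
    return datasets


def gen_bleach_trace(
    true_fret: float,
    donor_bleach_rate: float = 1e-3,
    counts_scale: float = 1e5,
    noise: NoiseSpec = NoiseSpec(),
    dt: float = 0.2,
    windows: tuple[float, float, float, float] = (0.0, 60.0, 80.0, 140.0),
) -> BleachTrace:
    """Synthetic donor-emission trace with a bleach step at ``true_fret``.

    The unquenched donor level decays linearly at ``donor_bleach_rate``
    (fraction per second) under continuous excitation; before acceptor
    bleaching the donor is quenched by the factor (1 - true_fret), afterwards
    fully dequenched, so the step at the end of the bleach window inverts to
    the generating efficiency exactly at zero noise.
    """
    if not 0.0 <= true_fret < 1.0:
        raise ValueError("true_fret must lie in [0, 1)")
    t0, t1, t2, t3 = windows
    t = np.arange(t0, t3, dt)
    donor = counts_scale * np.clip(1.0 - donor_bleach_rate * (t - t0), 0.0, None)
    quench = np.where(
        t < t1,
        1.0 - true_fret,
        np.where(t < t2, 1.0 - true_fret * (t2 - t) / (t2 - t1), 1.0),
    )
    expected = donor * quench
    rng = noise.rng()
    if noise.trace_noise == "poisson":
        counts = rng.poisson(expected).astype(float)
    elif noise.trace_noise == "gaussian":
        counts = np.clip(expected + rng.normal(0, noise.trace_gauss_sd, t.shape), 0, None)
    else:
        counts = expected
    return BleachTrace(
        t=t,
        cfp_counts=counts,
        pre_window=(t0, t1),
        bleach_window=(t1, t2),
        post_window=(t2, t3),
    )


def gen_growth_curve(
    mu: float,
    od0: float,
    horizon: float,
    noise: NoiseSpec = NoiseSpec(),
    n_points: int = 20,
    od_cv: float = 0.0,
) -> pd.DataFrame:
    """Exponential OD600 growth curve OD(t) = od0 exp(mu t), mu in 1/min.

    Multiplicative lognormal noise with coefficient of variation ``od_cv``;
    a log-linear fit to the noise-free curve returns ``mu`` exactly.
    """
    if od0 <= 0:
        raise ValueError("od0 must be positive")
    t = np.linspace(0.0, horizon, n_points)
    od = od0 * np.exp(mu * t)
    if od_cv > 0:
        rng = noise.rng()
        sigma = np.sqrt(np.log1p(od_cv**2))
        od = od * rng.lognormal(-(sigma**2) / 2.0, sigma, size=t.shape)
    return pd.DataFrame({"t_min": t, "od": od})


def gen_single_cell_population(
    E_true: float,
    cal: EFretCalibration,
    n_cells: int = 100,
    noise: NoiseSpec = NoiseSpec(),
    mean_donor: float = 1000.0,
    mean_acceptor: float = 800.0,
    expression_cv: float = 0.2,
    residual_acceptor_fraction: float = 0.05,
) -> tuple[SingleCellIntensities, SingleCellIntensities, SingleCellIntensities]:
    """Synthetic three-cube intensities at efficiency ``E_true``.

    Returns (fret_population, donor_only, acceptor_only).  Per-cell
    expression levels are lognormal; channel intensities satisfy the E-FRET
    inversion before measurement noise: I_DD = donor (1 - E), sensitized
    emission Fc = G donor E, I_DA = Fc + a I_AA + d I_DD.  The FRET
    population carries post-bleach channels (acceptor reduced to
    ``residual_acceptor_fraction``, donor fully dequenched) for G-factor
    calibration.  At zero noise ``e_fret`` returns ``E_true`` for every cell.
    """
    if not 0.0 <= E_true < 1.0:
        raise ValueError("E_true must lie in [0, 1)")
    rng = noise.rng()
    sigma = np.sqrt(np.log1p(expression_cv**2))

    def expression(mean, size):
        return mean * rng.lognormal(-(sigma**2) / 2.0, sigma, size=size)

    def measure(x):
        if noise.intensity_cv == 0:
            return np.asarray(x, dtype=float)
        return np.asarray(x) * (1.0 + rng.normal(0, noise.intensity_cv, np.shape(x)))

    donor = expression(mean_donor, n_cells)
    acceptor = expression(mean_acceptor, n_cells)
    i_dd = donor * (1.0 - E_true)
    fc = cal.G * donor * E_true
    i_aa = acceptor
    i_da = fc + cal.a * i_aa + cal.d * i_dd
    i_aa_post = residual_acceptor_fraction * acceptor
    i_dd_post = donor
    i_da_post = cal.a * i_aa_post + cal.d * i_dd_post  # FRET abolished
    fret_pop = SingleCellIntensities(
        I_DD=measure(i_dd),
        I_DA=measure(i_da),
        I_AA=measure(i_aa),
        I_DD_post=measure(i_dd_post),
        I_DA_post=measure(i_da_post),
        I_AA_post=measure(i_aa_post),
    )

    donor_d = expression(mean_donor, n_cells)
    donor_only = SingleCellIntensities(
        I_DD=measure(donor_d),
        I_DA=measure(cal.d * donor_d),
        I_AA=np.zeros(n_cells),
    )
    acc_a = expression(mean_acceptor, n_cells)
    acceptor_only = SingleCellIntensities(
        I_DD=np.zeros(n_cells),
        I_DA=measure(cal.a * acc_a),
        I_AA=measure(acc_a),
    )
    return fret_pop, donor_only, acceptor_only
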