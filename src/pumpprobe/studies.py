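"""Reference study designs and the parameter-recovery experiment.

``phra_design_suite`` assembles the stimulation, supernatant-bioassay, dose
and competition panels used to characterize the PhrA-RapA-Spo0F reporter
(short protocols without growth); ``phra_recovery_panel`` the long FRET
recovery time course in a growing culture.  ``parameter_recovery_study``
generates synthetic datasets from the best-fit truth and re-estimates the
parameters with the staged fit, once per seed, to quantify estimator
performance under replicate noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import (
    ExperimentDataset,
    RecoveryDesign,
    SupernatantAssay,
    staged_fit,
)
from .model_core import ModelParameters, phra_best_fit
from .protocols import BioassayDesign, StimulationDesign
from .synthetic import NoiseSpec, gen_fret_dataset

#: Measured culture growth rate (1/min) for the recovery experiment.
RECOVERY_MU = 0.58 / 60.0
#: Fitted intracellular degradation rate (1/min) used as generator truth.
RECOVERY_LAMBDA_I = 0.63 / 60.0

ACTIVATION_TIMES_MIN = (1.5, 2.0, 3.0, 4.0, 6.0, 10.0, 15.0)
DOSE_SERIES_NM = (1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0)
COMPETITION_UM = (0.0, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0)
RECOVERY_TIMES_MIN = (0.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0, 150.0, 180.0)


def phra_design_suite(n_e: int | None = None) -> list[tuple[str, list, int]]:
    """Short-protocol panels: (tag, designs, n_e) triples.

    Panels: activation time course at 10 nM with its paired supernatant
    bioassay, a dose series at fixed 6-min exposure, and competition series
    at 10 µM and 10 nM stimulus against increasing competitor.  Default
    replicate counts follow the corresponding experiments (9/9/10/5/5);
    passing ``n_e`` overrides all panels.
    """
    activation = [
        StimulationDesign(c_stim=10e-9, od=1.6, t_s=t) for t in ACTIVATION_TIMES_MIN
    ]
    bioassay = [
        SupernatantAssay(stim=d, bio=BioassayDesign()) for d in activation
    ]
    dose = [
        StimulationDesign(c_stim=c * 1e-9, od=1.6, t_s=6.0) for c in DOSE_SERIES_NM
    ]
    comp_high = [
        StimulationDesign(c_stim=10e-6, c_comp=c * 1e-6, od=1.6, t_s=6.0)
        for c in COMPETITION_UM
    ]
    comp_low = [
        StimulationDesign(c_stim=10e-9, c_comp=c * 1e-6, od=1.6, t_s=6.0)
        for c in COMPETITION_UM
    ]
    suite = [
        ("activation", activation, 9),
        ("activation_bioassay", bioassay, 9),
        ("dose_series", dose, 10),
        ("competition_10uM", comp_high, 5),
        ("competition_10nM", comp_low, 5),
    ]
    if n_e is not None:
        suite = [(tag, designs, n_e) for tag, designs, _ in suite]
    return suite


def phra_recovery_panel(n_e: int | None = None) -> tuple[str, list, int]:
    """FRET recovery time course in a growing culture (10 nM stimulus)."""
    designs = [
        RecoveryDesign(t=t, c_stim=10e-9, od=1.6, mu=RECOVERY_MU)
        for t in RECOVERY_TIMES_MIN
    ]
    return ("recovery", designs, n_e if n_e is not None else 4)


def generate_phra_datasets(
    noise: NoiseSpec,
    truth: ModelParameters | None = None,
    n_e: int | None = None,
) -> tuple[list[ExperimentDataset], ExperimentDataset]:
    """(global datasets, recovery dataset) generated from ``truth``."""
    if truth is None:
        truth = phra_best_fit()
    global_sets = gen_fret_dataset(truth, phra_design_suite(n_e), noise)
    recovery_truth = truth.with_(lambda_i=RECOVERY_LAMBDA_I)
    (recovery_set,) = gen_fret_dataset(
        recovery_truth, [phra_recovery_panel(n_e)], noise
    )
    return global_sets, recovery_set


def parameter_recovery_study(
    n_replicates: int = 20,
    noise_sd: float = 0.006,
    n_e: int = 5,
    seed: int = 0,
    n_starts: int = 8,
    truth: ModelParameters | None = None,
) -> pd.DataFrame:
    """Repeated synthetic-data generation and staged refitting.

    For each replicate a fresh noisy dataset suite is generated from the
    best-fit truth (replicate SD ``noise_sd``, ``n_e`` replicates per
    condition) and the staged fit (global stage, then the one-dimensional
    intracellular-degradation fit) is run from Latin-hypercube starts.
    Returns one row per replicate with the recovered parameters and SSR.
    """
    if truth is None:
        truth = phra_best_fit()
    rows = []
    base = np.random.SeedSequence(seed)
    child_seeds = base.generate_state(2 * n_replicates) % (2**31 - 1)
    for r in range(n_replicates):
        data_seed = int(child_seeds[2 * r])
        fit_seed = int(child_seeds[2 * r + 1])
        noise = NoiseSpec(fret_sd=noise_sd, seed=data_seed)
        global_sets, recovery_set = generate_phra_datasets(noise, truth, n_e=n_e)
        fit = staged_fit(
            global_sets, recovery_set, n_starts=n_starts, seed=fit_seed
        )
        row = {"replicate": r, "data_seed": data_seed, "ssr": fit.ssr}
        row.update(fit.theta_hat)
        rows.append(row)
    return pd.DataFrame(rows)
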