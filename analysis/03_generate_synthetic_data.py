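#!/usr/bin/env python
"""Generate the synthetic measurement suite used by the downstream fits.

Emulates every record the pipeline consumes: condition-level FRET means for
the activation/bioassay/dose/competition panels and the recovery time course
(Gaussian replicate noise, SD 0.006), an exponential OD600 growth curve, a
photon-counting bleach trace, and a three-cube single-cell population with
its calibration samples.  All outputs are seeded and written under results/.
"""

import numpy as np
import pandas as pd

from pumpprobe.fret_quant import EFretCalibration
from pumpprobe.io import save_datasets, save_params, write_table
from pumpprobe.model_core import phra_best_fit
from pumpprobe.studies import RECOVERY_MU, generate_phra_datasets
from pumpprobe.synthetic import (
    NoiseSpec,
    gen_bleach_trace,
    gen_growth_curve,
    gen_single_cell_population,
)

SEED = 0


def main():
    noise = NoiseSpec(fret_sd=0.006, seed=SEED)
    global_sets, recovery = generate_phra_datasets(noise)
    meta = {"seed": SEED, "fret_sd": noise.fret_sd}
    save_datasets(global_sets, "results/synthetic/fret_datasets.csv", meta)
    save_datasets([recovery], "results/synthetic/recovery_dataset.csv", meta)
    save_params(phra_best_fit(), "results/synthetic/generator_params.yaml")
    n_obs = sum(len(ds) for ds in global_sets)
    print(f"wrote {n_obs} short-protocol observations in "
          f"{len(global_sets)} panels + {len(recovery)} recovery time points")

    growth = gen_growth_curve(RECOVERY_MU, od0=1.6, horizon=180.0,
                              noise=noise, od_cv=0.01)
    write_table(growth, "results/synthetic/growth_curve.csv", {"seed": SEED})

    trace = gen_bleach_trace(0.112, donor_bleach_rate=1e-3, counts_scale=1e5,
                             noise=noise)
    write_table(
        pd.DataFrame({"t_s": trace.t, "counts": trace.cfp_counts}),
        "results/synthetic/bleach_trace.csv",
        {"true_fret": 0.112, "seed": SEED},
    )

    cal = EFretCalibration(a=0.3, d=0.5, G=2.5)
    pop, donor_only, acceptor_only = gen_single_cell_population(
        0.11, cal, n_cells=100, noise=noise
    )
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(100),
            "I_DD": pop.I_DD, "I_DA": pop.I_DA, "I_AA": pop.I_AA,
            "I_DD_post": pop.I_DD_post, "I_DA_post": pop.I_DA_post,
            "I_AA_post": pop.I_AA_post,
        }
    )
    write_table(cells, "results/synthetic/single_cells.csv",
                {"E_true": 0.11, "a": cal.a, "d": cal.d, "G": cal.G, "seed": SEED})
    print("wrote growth curve, bleach trace, and single-cell intensity tables")


if __name__ == "__main__":
    main()
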