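#!/usr/bin/env python
"""Quantify FRET from the synthetic raw-fluorescence records.

Runs the acceptor-photobleaching estimator (robust donor-bleach correction,
extrapolation to the bleach end) on the synthetic photon-counting trace, and
the three-cube E-FRET pipeline (bleed-through coefficients from single-label
populations, G-factor from the pre/post bleach pair, per-cell apparent
efficiencies) on the synthetic single-cell table.  Compares every estimate
with its generator truth.
"""

import numpy as np

from pumpprobe.fret_quant import (
    EFretCalibration,
    SingleCellIntensities,
    bleedthrough_coefficients,
    e_fret,
    fret_from_bleach_trace,
    g_factor,
)
from pumpprobe.synthetic import NoiseSpec, gen_bleach_trace, gen_single_cell_population


def main():
    res = fret_from_bleach_trace(
        gen_bleach_trace(0.112, donor_bleach_rate=1e-3, counts_scale=1e5,
                         noise=NoiseSpec(trace_noise="poisson", seed=0))
    )
    print(f"bleach trace: FRET = {res.fret_percent:.2f}% "
          f"(truth 11.20%), significant = {res.significant}")

    cal = EFretCalibration(a=0.3, d=0.5, G=2.5)
    pop, donor_only, acceptor_only = gen_single_cell_population(
        0.11, cal, n_cells=400, noise=NoiseSpec(intensity_cv=0.02, seed=0)
    )
    a, d = bleedthrough_coefficients(donor_only, acceptor_only)
    post = SingleCellIntensities(I_DD=pop.I_DD_post, I_DA=pop.I_DA_post,
                                 I_AA=pop.I_AA_post)
    g = g_factor(pop, post, a, d)
    e = e_fret(pop, EFretCalibration(a=a, d=d, G=g))
    print(f"bleed-through: a = {a:.4f} (truth {cal.a}), d = {d:.4f} (truth {cal.d})")
    print(f"G-factor: {g:.3f} (truth {cal.G})")
    print(f"E-FRET: mean E_app = {np.nanmean(e):.4f} +/- {np.nanstd(e):.4f} "
          "(truth 0.1100)")


if __name__ == "__main__":
    main()
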