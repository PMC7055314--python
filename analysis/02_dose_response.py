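#!/usr/bin/env python
"""Dose-response analysis and derived kinetic quantities at the best fit.

Computes the characteristic signal-processing time tau = 1/(mu + lambda_i),
the per-cell import rate at the physiological extracellular concentration
(~0.4 nM), the per-cell signal uptake N_in over the integration time, the
minimal-FRET surface over (stimulus concentration x cell density), and the
collapsed dose-response curve with its half-maximal dose D50.
"""

import numpy as np

from pumpprobe.io import write_table
from pumpprobe.model_core import intracellular_timescale, phra_best_fit
from pumpprobe.protocols import (
    dose_response_curve,
    dose_response_surface,
    signal_integration_uptake,
)
from pumpprobe.studies import RECOVERY_LAMBDA_I, RECOVERY_MU


def main():
    p = phra_best_fit(mu=RECOVERY_MU, lambda_i=RECOVERY_LAMBDA_I)

    tau = intracellular_timescale(p.mu, p.lambda_i)
    c_e = 0.4e-9
    import_rate = p.v_max * c_e / (p.K_M + c_e)
    n_in = signal_integration_uptake(c_e, p)
    print(f"signal-processing time tau = {tau:.1f} min")
    print(f"per-cell import rate at C_e = 0.4 nM: {import_rate:.0f} molecules/min")
    print(f"per-cell uptake over tau (dose estimate): N_in = {n_in:.3g} molecules")

    quiescent = phra_best_fit()  # short protocols: no growth/degradation
    surf = dose_response_surface(
        quiescent, C_grid=np.logspace(-9, -5, 9), od_grid=[0.2, 0.4, 0.8, 1.6, 3.2]
    )
    write_table(surf, "results/dose_response_surface.csv", {"V_i_L": quiescent.V_i})

    curve, d50 = dose_response_curve(quiescent, np.logspace(3, 6, 41))
    write_table(curve, "results/dose_response_curve.csv", {"D50_molecules": d50})
    print(f"half-maximal dose D50 = {d50:.3g} molecules per cell")
    print(f"(N_in / D50 = {n_in / d50:.2f}: physiological supernatant levels "
          "sit near the half-maximal dose)")


if __name__ == "__main__":
    main()
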