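# pumpprobe

Modeling and inference for **pump–probe signaling networks** — bacterial
cell–cell communication systems in which extracellular signaling peptides are
actively imported ("pumped") into the cytoplasm by an oligopeptide permease
before an intracellular receptor reads them out ("probes").  The package was
built around the PhrA–RapA–Spo0F pathway of *Bacillus subtilis*, where
peptide-induced changes in the RapA–Spo0F interaction are monitored by FRET,
but the model and tooling apply to RRNPP-type export–import circuits in
general.

It is aimed at systems biologists who want to (i) explore what such a network
can compute — quorum sensing, ratiometric (population-fraction) sensing, or
chronometric (delay-timer) control, (ii) fit the network model to FRET
dose–response and time-course data, and (iii) quantify FRET from raw
acceptor-photobleaching or three-cube microscopy records.

## The model

A well-mixed population of $N_c$ cells in volume $V_e$ grows exponentially,
$N_c(t) = N_c^0 e^{\mu t}$.  A fraction $f$ of cells exports signal at rate
$\pi$ (molecules/min); every cell imports peptides through a shared
Michaelis–Menten transporter (maximal flux $v_\max$, half-saturation $K_M$),
with competing peptides entering the same saturation denominator:

$$\frac{dC_i^s}{dt} = \frac{v_\max}{V_i N_A}\,\frac{C_e^s}{K_M + C_e} - (\lambda_i + \mu)\,C_i^s$$

$$\frac{dC_e^s}{dt} = \frac{\pi f N_c}{V_e N_A} - \frac{N_c\, v_\max}{V_e N_A}\,\frac{C_e^s}{K_M + C_e} - \lambda_e C_e^s$$

with the analogous equation for the total peptide pool $C_e = C_e^s + C_e^o$.
Transduction is instantaneous and Hill-shaped; the FRET readout is

$$\mathrm{FRET}(t) = \mathrm{FRET}_0 - \Delta\mathrm{FRET}\,
\frac{C_i^n}{EC_{50}^n + C_i^n}.$$

The sign of the effective net production rate $\pi_{\mathrm{eff}} = f\pi -
v_\max$ separates quorum sensing (positive: extracellular signal tracks
density) from ratiometric sensing (negative: the extracellular concentration
settles onto $C_e^* = K_M f\pi/(v_\max - f\pi)$, independent of density);
saturated import with a switch-like output yields chronometric control.

Inference minimizes the plain sum of squared residuals over all panels
(damped least squares, multi-start), fits the intracellular degradation rate
$\lambda_i$ separately from a recovery time course, and reports
profile-likelihood intervals from the F-statistic constraint
$\mathrm{SSR}(\theta) \le \mathrm{SSR}(\hat\theta)\,[1 + \tfrac{p}{n-p}
F^{\alpha}_{p,n-p}]$ plus case-resampling bootstrap bands.

## Worked example

```python
import numpy as np
from pumpprobe import phra_best_fit, StimulationDesign, simulate_stimulation
from pumpprobe.protocols import dose_response_curve

params = phra_best_fit()                      # fitted PhrA-RapA constants
out = simulate_stimulation(StimulationDesign(c_stim=10e-9, od=1.6, t_s=6.0), params)
print(f"FRET after 6 min at 10 nM: {out.fret:.4f}")
curve, d50 = dose_response_curve(params, np.logspace(3, 6, 31))
print(f"half-maximal dose D50 = {d50:.3g} molecules per cell")
```

prints

```
FRET after 6 min at 10 nM: 0.0752
half-maximal dose D50 = 2.57e+04 molecules per cell
```

— a 6-min, 10 nM stimulus at OD 1.6 drives FRET from its 11.0% baseline down
to ~7.5% (the cells have taken up nearly the whole dose of ~3.2×10⁴
molecules per cell), and half-maximal inhibition requires ~2.6×10⁴ available
molecules per cell.

The numbered scripts under `analysis/` walk through the full study:
regime simulations (`01`), dose–response and derived kinetic quantities
(`02`), synthetic-data generation (`03`), model fitting with profile and
bootstrap intervals (`04`), FRET quantification from raw records (`05`), and
the parameter-recovery study (`06`).  Each writes its tables under
`results/`.  A thin CLI (`pumpprobe simulate|regimes|dose-response|fit|
fret-quant|synth`) wraps the same functions.

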