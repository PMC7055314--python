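# Methods

## Model and assumptions

The pump–probe model describes a well-mixed, exponentially growing population
exchanging a signaling peptide with its medium.  State variables are the
intracellular signal concentration `C_i_s`, the extracellular signal
concentration `C_e_s`, and the total extracellular peptide `C_e_tot` (signal
plus any competing peptide); all are molar, time is in minutes.  Import
follows Michaelis–Menten kinetics through a single shared transporter: the
saturation denominator uses the *total* peptide concentration (all
pentapeptides are transported with the same efficiency), while only the
signal fraction feeds the intracellular pool.  Intracellular signal is lost
to degradation (`lambda_i`) and growth dilution (`mu`); extracellular peptide
may degrade at `lambda_e` (zero on protocol timescales — the peptide is
stable in spent medium for hours).

Assumptions worth keeping in mind:

* **Fast receptor equilibration.**  Receptor binding and downstream
  transduction are treated as instantaneous relative to transport, so output
  and FRET are static Hill functions of `C_i`.  No explicit receptor-ligand
  kinetics are modeled.
* **Well-mixed, identical cells.**  No spatial structure, no cell-to-cell
  variability in transport or expression.
* **Analytic growth.**  `N_c(t) = N_c0 * exp(mu t)` is substituted into the
  equations rather than integrated as a fourth state.
* **Production feeds both peptide pools.**  The signal is itself a peptide,
  so production enters the total-peptide balance as well; with `pi = 0`
  (every fitted protocol) the total-pool equation reduces to pure
  consumption plus decay.

## Parameters, units, defaults

| parameter | unit | default | meaning |
|---|---|---|---|
| `v_max` | molecules/min | 1.9e5 | maximal per-cell import flux |
| `K_M` | mol/L | 140e-9 | transport half-saturation |
| `pi` | molecules/min | 0 | per-producer signal export rate |
| `f` | — | 0 | producer fraction |
| `lambda_e`, `lambda_i`, `mu` | 1/min | 0 | extracellular/intracellular loss, growth |
| `V_e` | L | 500e-6 | medium volume (stimulation tube) |
| `V_i` | L | 1.12e-15 | single-cell volume (see below) |
| `EC50` | mol/L | 38e-6 | half-maximal intracellular concentration |
| `n` | — | 1.4 | Hill coefficient |
| `FRET0`, `dFRET` | fraction | 0.110, 0.064 | baseline FRET, maximal drop |

Particle fluxes (`v_max`, `pi`) are converted to molar fluxes with Avogadro's
number.  Cell counts come from OD600 at 1.19e8 cells/mL per OD unit (9.5e7
cells at OD 1.6 in 500 µL).

**Cell volume.**  `V_i` comes from a rod geometry — cylinder of length `L`
with hemispherical caps of diameter `D`, `V_i = pi (L-D)(D/2)^2 +
(4/3) pi (D/2)^3` — with defaults `L = 2.5 µm`, `D = 0.8 µm` (1.12 fL),
typical of *B. subtilis* in minimal medium.  This choice matters: `EC50`
estimates and the dose scale are inversely proportional to `V_i`, and the
default is the value consistent with the system's half-maximal dose
(~2.4e4 molecules per cell) and its response to a 10 nM stimulus at OD 1.6
(FRET ~7.3%).  `V_i` is recorded with every fit result.

The printed Hill denominator for the FRET response is implemented in the
standard form `EC50^n + C_i^n`, consistent with the output Hill function.

## Numerics

* **ODE integration**: `scipy.integrate.solve_ivp` with LSODA, `rtol 1e-8`,
  `atol 1e-15 mol/L`; states clipped at zero after the solve to absorb
  roundoff.  With all gain/loss terms off, total signal molecules are
  conserved to better than 1e-6 relative (tested).
* **Closed-form depletion fast path.**  Without growth, degradation and
  production, total peptide obeys the integrated Michaelis–Menten law
  `K_M ln(C0/C) + (C0 - C) = rate * t`, and the signal:total ratio is
  invariant because both pools are consumed proportionally.  The implicit
  equation is solved by bracketed root-finding in log-concentration (robust
  down to depletion far below floating-point epsilon).  Stimulation,
  bioassay and dose protocols use this path by default; it agrees with the
  ODE route to solver tolerance (tested) and makes repeated fitting cheap.
* **Depletion endpoint** for "minimal FRET": extracellular total below
  1e-15 mol/L or 24 h, whichever comes first.
* **Washes** set extracellular peptide to zero and leave `C_i` untouched;
  the 1-min centrifugation is counted as uptake at full rate (`t_s`
  includes it).
* **Delay times** are located by inverse interpolation of the output on a
  2000-point grid; a threshold of 0.5·O_max is the default switch
  criterion.

## Fitting

Stage one estimates (`v_max`, `K_M`, `EC50`, `FRET0`, `dFRET`, `n`) by
minimizing the unweighted SSR over all short-protocol panels with growth and
degradation frozen at zero; stage two fits `lambda_i` alone to the recovery
time course in a growing culture (measured `mu` supplied per design).  Scale
parameters (`v_max`, `K_M`, `EC50`, `lambda_i`) are optimized on log10 scale;
`FRET0`, `dFRET` on [0, 1] and `n` on [0.5, 5].  The optimizer is
`scipy.optimize.least_squares` (trust-region reflective) from 16
Latin-hypercube starts by default (a single documented start is not
robustness-guaranteed); the data enter as condition-level means, and an
optional 1/sd² weighting flag is deliberately absent — residuals are plain.

Profile-likelihood intervals march each parameter outward from the optimum,
re-optimizing the rest, and refine the crossing of the F-constraint ceiling
by bracketed root finding; endpoints satisfy the constraint to ~1e-6
relative.  An interval that never crosses before its box bound is reported
open (±inf) with a warning.  Bootstrap bands use case resampling within each
panel, refitting from the full-data optimum (B = 1000 by default; refits
that fail are skipped and counted, with an error above 20% failures).
Percentile bands on nonlinear fits undercover mildly (~88% observed at
nominal 95% in the round-trip tests); this is a known property of the
method, not a defect of the implementation.

## Synthetic data: what it does and does not emulate

The generators produce every input the pipeline consumes, each the exact
inverse of its quantifier at zero noise:

* **FRET panels** — model-true FRET per condition plus Gaussian replicate
  noise (SD 0.006 on the FRET scale, matching the ~0.6-percentage-point
  scatter of the population assays), reported as replicate mean ± SD.
* **Bleach traces** — linear donor bleaching under continuous excitation,
  quenching by (1 − FRET) before the bleach step, Poisson photon counting
  at ~1e5 counts/bin.
* **Growth curves** — exponential OD with multiplicative lognormal noise.
* **Single-cell three-cube intensities** — lognormal expression variability
  (CV 20%), bleed-through per the a/d definitions, multiplicative channel
  noise (CV 2%), and post-bleach counterparts with 5% residual acceptor.

Not emulated: day-to-day instrument drift, correlated replicate errors,
cell-to-cell transport variability, segmentation artifacts, or expression
induction variability.  Passing round-trip tests therefore demonstrates
estimator correctness and precision under the stated noise model, not
robustness to structured experimental error.

## Study design of the recovery experiment

The parameter-recovery study mirrors the measurement panels: a 10 nM
activation time course (7 exposure times, with paired supernatant
bioassays), a 9-point dose series at 6-min exposure, competition series at
10 µM and 10 nM stimulus against 8 competitor levels, and a 10-point
recovery time course in a growing culture (`mu` = 0.58/h, generator
`lambda_i` = 0.63/h).  Twenty replicates at replicate-SD 0.006 and n_e = 5,
staged fit from 8 Latin-hypercube starts per replicate — problem sizes
chosen to characterize the estimator at desk scale while the zero-noise
variant checks exactness.

## Known limitations

* The regime classifier uses a simple sign/threshold rule (`pi_eff`, Hill
  coefficient ≥ 5, saturating signal); it does not locate analytic regime
  boundaries or bifurcations.
* Chronometric switch times are only approximately independent of the
  social context: from a zero-signal start, the lag until the extracellular
  pool saturates import scales with 1/(f·N0) and shifts the delay by up to
  tens of minutes across inoculum/producer-fraction grids (measured ~7%
  across a factor-2 inoculum change at the reference parameters, more at
  small f).  The delay is insensitive to inoculum *doubling* at f = 1
  (<5%), and tunable over hours by `lambda_i`.
* E-FRET reverse bleed-through terms (donor signal in the acceptor channel
  and vice versa) are not implemented; they are negligible for typical
  CFP/YFP filter sets.
* Bioassay cell density defaults to the stimulation density; the 10×
  concentrate is assumed to restore exactly 1× on dilution.
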