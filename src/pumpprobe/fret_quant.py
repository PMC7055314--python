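"""FRET efficiency quantification from raw fluorescence records.

Two measurement modes are supported:

* **Acceptor photobleaching** of a cell population monitored by a photon
  counting tube: donor (CFP) emission is recorded before and after the
  acceptor is photobleached; the efficiency is the relative increase in donor
  emission, FRET = (CFP_post - CFP_pre)/CFP_post * 100%.  Because the donor
  itself bleaches slowly under continuous excitation, both windows are fitted
  with a robust line and extrapolated to the end of the bleach period.

* **Three-cube E-FRET** on single cells: intensities in the donor (I_DD),
  FRET (I_DA) and acceptor (I_AA) channels are combined after bleed-through
  correction into the apparent efficiency E_app = Fc/(Fc + G*I_DD) with
  Fc = I_DA - a*I_AA - d*I_DD, where the G-factor converts sensitized
  acceptor emission into donor-dequenching units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import statsmodels.api as sm

from .exceptions import CalibrationError, InvalidTraceError

#: Relative CFP increase (percent) above which a bleach-step is scored as
#: genuine donor-acceptor FRET rather than noise.
SIGNIFICANT_FRET_PERCENT = 0.6


@dataclass
class BleachTrace:
    """A donor-emission photobleaching trace.

    ``t`` in seconds, ``cfp_counts`` photon counts per bin.  The pre, bleach
    and post windows must be contiguous and nonoverlapping: pre = [t0, t1),
    bleach = [t1, t2), post = [t2, t3].
    """

    t: np.ndarray
    cfp_counts: np.ndarray
    pre_window: tuple[float, float] = (0.0, 60.0)
    bleach_window: tuple[float, float] = (60.0, 80.0)
    post_window: tuple[float, float] = (80.0, 140.0)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.cfp_counts = np.asarray(self.cfp_counts, dtype=float)
        if self.t.shape != self.cfp_counts.shape:
            raise ValueError("t and cfp_counts must have matching shapes")
        if np.any(self.cfp_counts < 0):
            raise ValueError("counts must be nonnegative")
        w = (*self.pre_window, *self.bleach_window, *self.post_window)
        if not (w[0] < w[1] == w[2] < w[3] == w[4] < w[5]):
            raise ValueError("windows must be contiguous and ordered")

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        return (self.t >= lo) & (self.t < hi)


class BleachFret(NamedTuple):
    fret_percent: float
    cfp_pre: float
    cfp_post: float
    significant: bool


def _linear_fit_eval(t: np.ndarray, y: np.ndarray, t_eval: float, robust: bool) -> float:
    """Fit y ~ t (robust IRLS with a redescending weight, or OLS) and
    evaluate the line at ``t_eval``."""
    if np.ptp(t) == 0:
        raise InvalidTraceError("degenerate fit: no time variation in window")
    X = sm.add_constant(t)
    ols = sm.OLS(y, X).fit()
    if robust and ols.ssr > 1e-12 * max(1.0, float(np.max(np.abs(y)))) ** 2:
        fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit(
            maxiter=50, tol=1e-8
        )
        params = fit.params
    else:
        # perfect (or near-perfect) line: IRLS weights are undefined, OLS exact
        params = ols.params
    return float(params[0] + params[1] * t_eval)


def fret_from_bleach_trace(trace: BleachTrace, robust: bool = True) -> BleachFret:
    """FRET efficiency (percent) from an acceptor-photobleaching trace.

    Robust lines are fitted to the pre- and post-bleach windows and both are
    extrapolated to the end of the bleach window, where the donor-bleaching
    baselines coincide; the efficiency is the relative donor dequenching
    (CFP_post - CFP_pre)/CFP_post * 100.  A result above 0.6% is scored
    significant.
    """
    pre = trace.window_mask(trace.pre_window)
    post = trace.window_mask((trace.post_window[0], trace.post_window[1] + 1e-9))
    if pre.sum() < 10 or post.sum() < 10:
        raise InvalidTraceError("need at least 10 samples in each window")
    t_end = trace.bleach_window[1]
    cfp_pre = _linear_fit_eval(trace.t[pre], trace.cfp_counts[pre], t_end, robust)
    cfp_post = _linear_fit_eval(trace.t[post], trace.cfp_counts[post], t_end, robust)
    if cfp_post <= 0:
        raise InvalidTraceError(f"extrapolated CFP_post = {cfp_post:.3g} <= 0")
    fret = (cfp_post - cfp_pre) / cfp_post * 100.0
    return BleachFret(
        fret_percent=float(fret),
        cfp_pre=float(cfp_pre),
        cfp_post=float(cfp_post),
        significant=bool(fret > SIGNIFICANT_FRET_PERCENT),
    )


@dataclass
class SingleCellIntensities:
    """Background/autofluorescence-corrected channel intensities.

    Scalars or aligned arrays (one entry per cell); ``*_post`` fields hold
    post-acceptor-bleach counterparts when available.  Corrected intensities
    may legitimately be slightly negative and are kept unclipped.
    """

    I_DD: np.ndarray
    I_DA: np.ndarray
    I_AA: np.ndarray
    I_DD_post: np.ndarray | None = None
    I_DA_post: np.ndarray | None = None
    I_AA_post: np.ndarray | None = None

    def __post_init__(self):
        for name in ("I_DD", "I_DA", "I_AA", "I_DD_post", "I_DA_post", "I_AA_post"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, v)

    @property
    def has_negative(self) -> bool:
        return bool(
            np.any(self.I_DD < 0) or np.any(self.I_DA < 0) or np.any(self.I_AA < 0)
        )


@dataclass(frozen=True)
class EFretCalibration:
    """Bleed-through coefficients and G-factor for three-cube E-FRET."""

    a: float  # acceptor bleed-through into the FRET channel
    d: float  # donor bleed-through into the FRET channel
    G: float  # sensitized emission per unit donor dequenching

    def __post_init__(self):
        if self.a < 0 or self.d < 0:
            raise ValueError("bleed-through coefficients must be nonnegative")
        if self.G <= 0:
            raise ValueError("G-factor must be positive")


def correct_intensities(
    raw: SingleCellIntensities,
    background: dict[str, float] | float,
    autofluorescence: dict[str, float] | float,
) -> SingleCellIntensities:
    """Subtract per-channel background and cellular autofluorescence.

    The correction is a plain subtraction and therefore not idempotent:
    applying it twice over-subtracts.  Negative corrected intensities are
    retained (clipping would bias population means).
    """

    def per_channel(spec, channel):
        return spec.get(channel, 0.0) if isinstance(spec, dict) else float(spec)

    def fix(values, channel):
        if values is None:
            return None
        return values - per_channel(background, channel) - per_channel(
            autofluorescence, channel
        )

    return SingleCellIntensities(
        I_DD=fix(raw.I_DD, "I_DD"),
        I_DA=fix(raw.I_DA, "I_DA"),
        I_AA=fix(raw.I_AA, "I_AA"),
        I_DD_post=fix(raw.I_DD_post, "I_DD"),
        I_DA_post=fix(raw.I_DA_post, "I_DA"),
        I_AA_post=fix(raw.I_AA_post, "I_AA"),
    )


def bleedthrough_coefficients(
    donor_only: SingleCellIntensities,
    acceptor_only: SingleCellIntensities,
    floor: float = 1e-9,
) -> tuple[float, float]:
    """(a, d) bleed-through coefficients from single-label populations.

    a = mean over acceptor-only cells of I_DA/I_AA;
    d = mean over donor-only cells of I_DA/I_DD.
    Cells whose denominator is below ``floor`` times the population median
    magnitude are excluded with a warning.
    """

    def mean_ratio(num, den, label):
        num = np.atleast_1d(num)
        den = np.atleast_1d(den)
        scale = np.median(np.abs(den))
        keep = np.abs(den) > max(floor * scale, 1e-300)
        n_excluded = int((~keep).sum())
        if n_excluded:
            warnings.warn(
                f"{label}: excluded {n_excluded} cell(s) with near-zero "
                "denominator", stacklevel=3,
            )
        if not keep.any():
            raise CalibrationError(f"{label}: all cells excluded")
        return float(np.mean(num[keep] / den[keep]))

    a = mean_ratio(acceptor_only.I_DA, acceptor_only.I_AA, "acceptor-only (a)")
    d = mean_ratio(donor_only.I_DA, donor_only.I_DD, "donor-only (d)")
    return a, d


def e_fret(cell: SingleCellIntensities, cal: EFretCalibration):
    """Apparent FRET efficiency E_app per cell (NaN where undefined).

    Fc = I_DA - a*I_AA - d*I_DD is the sensitized emission; E_app =
    Fc/(Fc + G*I_DD).  The ratio structure makes E_app invariant under a
    common scaling of all intensities.  A nonpositive denominator (no donor
    signal) yields NaN with a warning.
    """
    fc = np.atleast_1d(cell.I_DA - cal.a * cell.I_AA - cal.d * cell.I_DD)
    den = fc + cal.G * np.atleast_1d(cell.I_DD)
    bad = den <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} cell(s) with nonpositive E-FRET denominator; "
            "returning NaN for those", stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(bad, np.nan, fc / np.where(bad, np.nan, den))
    return e if e.size > 1 else float(e[0])


def g_factor(
    pre: SingleCellIntensities,
    post: SingleCellIntensities,
    a: float,
    d: float,
    bleach_fraction: float = 0.2,
):
    """G-factor from matched pre/post acceptor-photobleach intensities.

    G = (Fc_pre - Fc_post) / (I_DD_post - I_DD): the loss of sensitized
    emission per unit of donor dequenching.  Requires substantial acceptor
    bleaching (I_AA_post < ``bleach_fraction`` * I_AA) and genuine donor
    dequenching (I_DD_post > I_DD).  For cell populations the numerator and
    denominator are pooled (summed) across cells before dividing: the
    per-cell dequenching difference is noisy, and a per-cell ratio estimator
    would be biased upward.
    """
    i_aa = np.atleast_1d(pre.I_AA)
    i_aa_post = np.atleast_1d(post.I_AA)
    if np.any(i_aa_post >= bleach_fraction * i_aa):
        warnings.warn(
            "acceptor not sufficiently bleached in some cells "
            f"(I_AA_post >= {bleach_fraction:.0%} of I_AA)", stacklevel=2,
        )
    fc_pre = np.atleast_1d(pre.I_DA) - a * i_aa - d * np.atleast_1d(pre.I_DD)
    fc_post = np.atleast_1d(post.I_DA) - a * i_aa_post - d * np.atleast_1d(post.I_DD)
    dequench = np.atleast_1d(post.I_DD) - np.atleast_1d(pre.I_DD)
    n_bad = int(np.sum(dequench <= 0))
    pooled_dequench = float(np.sum(dequench))
    if pooled_dequench <= 0:
        raise CalibrationError(
            "no donor dequenching (I_DD_post <= I_DD): cannot calibrate G"
        )
    if n_bad:
        warnings.warn(
            f"{n_bad} cell(s) without donor dequenching pooled into G",
            stacklevel=2,
        )
    return float(np.sum(fc_pre - fc_post) / pooled_dequench)
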