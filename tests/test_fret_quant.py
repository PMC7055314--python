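"""FRET quantification from bleach traces and three-cube intensities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pumpprobe.exceptions import CalibrationError, InvalidTraceError
from pumpprobe.fret_quant import (
    BleachTrace,
    EFretCalibration,
    SingleCellIntensities,
    bleedthrough_coefficients,
    correct_intensities,
    e_fret,
    fret_from_bleach_trace,
    g_factor,
)
from pumpprobe.synthetic import NoiseSpec, gen_bleach_trace, gen_single_cell_population

CAL = EFretCalibration(a=0.3, d=0.5, G=2.5)


class TestBleachTrace:
    def test_flat_trace_no_step(self):
        tr = gen_bleach_trace(0.0, donor_bleach_rate=0.0, noise=NoiseSpec(trace_noise="none"))
        res = fret_from_bleach_trace(tr)
        assert res.fret_percent == pytest.approx(0.0, abs=1e-9)
        assert not res.significant

    def test_plateau_arithmetic(self):
        # synthetic plateaus CFP_pre = 90, CFP_post = 100 -> FRET = 10%
        t = np.arange(0, 140.0, 0.5)
        counts = np.where(t < 60, 90.0, np.where(t < 80, 95.0, 100.0))
        tr = BleachTrace(t=t, cfp_counts=counts)
        res = fret_from_bleach_trace(tr)
        assert res.fret_percent == pytest.approx(10.0, abs=1e-9)
        assert res.cfp_pre == pytest.approx(90.0)
        assert res.cfp_post == pytest.approx(100.0)
        assert res.significant

    def test_noise_free_round_trip_with_donor_bleaching(self):
        tr = gen_bleach_trace(
            0.112, donor_bleach_rate=1e-3, noise=NoiseSpec(trace_noise="none")
        )
        res = fret_from_bleach_trace(tr)
        assert res.fret_percent == pytest.approx(11.2, abs=1e-6)

    def test_poisson_noise_recovery(self):
        # realistic photon counting at 1e5 counts per bin, 50 seeds
        errs = []
        for seed in range(50):
            tr = gen_bleach_trace(
                0.112, donor_bleach_rate=1e-3, counts_scale=1e5,
                noise=NoiseSpec(trace_noise="poisson", seed=seed),
            )
            errs.append(fret_from_bleach_trace(tr).fret_percent - 11.2)
        assert np.max(np.abs(errs)) < 0.3

    def test_scale_invariance(self):
        r1 = fret_from_bleach_trace(
            gen_bleach_trace(0.08, counts_scale=1e4, noise=NoiseSpec(trace_noise="none"))
        )
        r2 = fret_from_bleach_trace(
            gen_bleach_trace(0.08, counts_scale=2e4, noise=NoiseSpec(trace_noise="none"))
        )
        assert r1.fret_percent == pytest.approx(r2.fret_percent, abs=1e-9)

    def test_offset_in_post_window_shifts_fret(self):
        tr = gen_bleach_trace(0.10, noise=NoiseSpec(trace_noise="none"))
        post = tr.window_mask((tr.post_window[0], tr.post_window[1] + 1))
        counts = tr.cfp_counts.copy()
        counts[post] *= 1.02
        shifted = BleachTrace(
            t=tr.t, cfp_counts=counts, pre_window=tr.pre_window,
            bleach_window=tr.bleach_window, post_window=tr.post_window,
        )
        base = fret_from_bleach_trace(tr).fret_percent
        up = fret_from_bleach_trace(shifted).fret_percent
        assert up > base

    def test_too_few_samples_rejected(self):
        tr = gen_bleach_trace(0.1, dt=10.0, noise=NoiseSpec(trace_noise="none"))
        with pytest.raises(InvalidTraceError):
            fret_from_bleach_trace(tr)

    def test_significance_threshold(self):
        low = gen_bleach_trace(0.004, noise=NoiseSpec(trace_noise="none"))
        assert not fret_from_bleach_trace(low).significant
        high = gen_bleach_trace(0.0099, noise=NoiseSpec(trace_noise="none"))
        assert fret_from_bleach_trace(high).significant

    def test_robust_fit_resists_outliers(self):
        tr = gen_bleach_trace(0.112, noise=NoiseSpec(trace_noise="none"))
        counts = tr.cfp_counts.copy()
        counts[10] *= 3.0  # cosmic-ray style spike in the pre window
        spiked = BleachTrace(
            t=tr.t, cfp_counts=counts, pre_window=tr.pre_window,
            bleach_window=tr.bleach_window, post_window=tr.post_window,
        )
        robust = fret_from_bleach_trace(spiked, robust=True).fret_percent
        plain = fret_from_bleach_trace(spiked, robust=False).fret_percent
        assert abs(robust - 11.2) < abs(plain - 11.2)
        assert robust == pytest.approx(11.2, abs=0.05)


class TestBleedthrough:
    def test_exact_ratios(self):
        acc = SingleCellIntensities(
            I_DD=np.zeros(5), I_DA=0.3 * np.full(5, 800.0), I_AA=np.full(5, 800.0)
        )
        don = SingleCellIntensities(
            I_DD=np.full(5, 1000.0), I_DA=0.5 * np.full(5, 1000.0), I_AA=np.zeros(5)
        )
        a, d = bleedthrough_coefficients(don, acc)
        assert a == pytest.approx(0.3) and d == pytest.approx(0.5)

    def test_noisy_recovery(self):
        _, don, acc = gen_single_cell_population(
            0.11, CAL, n_cells=100, noise=NoiseSpec(intensity_cv=0.02, seed=4)
        )
        a, d = bleedthrough_coefficients(don, acc)
        assert a == pytest.approx(CAL.a, rel=0.01)
        assert d == pytest.approx(CAL.d, rel=0.01)

    def test_near_zero_denominators_excluded(self):
        acc = SingleCellIntensities(
            I_DD=np.zeros(3), I_DA=np.array([240.0, 240.0, 1.0]),
            I_AA=np.array([800.0, 800.0, 1e-15]),
        )
        don = SingleCellIntensities(
            I_DD=np.full(3, 1000.0), I_DA=np.full(3, 500.0), I_AA=np.zeros(3)
        )
        with pytest.warns(UserWarning):
            a, _ = bleedthrough_coefficients(don, acc)
        assert a == pytest.approx(0.3)

    def test_all_excluded_raises(self):
        acc = SingleCellIntensities(I_DD=0.0, I_DA=1.0, I_AA=0.0)
        don = SingleCellIntensities(I_DD=1000.0, I_DA=500.0, I_AA=0.0)
        with pytest.warns(UserWarning):
            with pytest.raises(CalibrationError):
                bleedthrough_coefficients(don, acc)


class TestEFret:
    def test_donor_only_cell_reads_zero(self):
        cell = SingleCellIntensities(I_DD=1000.0, I_DA=CAL.d * 1000.0, I_AA=0.0)
        assert e_fret(cell, CAL) == pytest.approx(0.0, abs=1e-12)

    def test_direct_arithmetic(self):
        # Fc = 100, G = 2, I_DD = 100 -> E = 100/(100+200) = 1/3
        cal = EFretCalibration(a=0.0, d=0.0, G=2.0)
        cell = SingleCellIntensities(I_DD=100.0, I_DA=100.0, I_AA=0.0)
        assert e_fret(cell, cal) == pytest.approx(1.0 / 3.0)

    def test_population_round_trip(self):
        pop, _, _ = gen_single_cell_population(
            0.11, CAL, n_cells=100, noise=NoiseSpec(intensity_cv=0.02, seed=9)
        )
        e = e_fret(pop, CAL)
        assert np.nanmean(e) == pytest.approx(0.11, abs=0.005)

    def test_zero_noise_exact_per_cell(self):
        pop, _, _ = gen_single_cell_population(
            0.11, CAL, n_cells=20, noise=NoiseSpec(intensity_cv=0.0, seed=0)
        )
        assert np.allclose(e_fret(pop, CAL), 0.11, atol=1e-12)

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_invariant_under_uniform_intensity_scaling(self, scale):
        cell = SingleCellIntensities(I_DD=900.0, I_DA=700.0, I_AA=750.0)
        scaled = SingleCellIntensities(
            I_DD=900.0 * scale, I_DA=700.0 * scale, I_AA=750.0 * scale
        )
        assert e_fret(scaled, CAL) == pytest.approx(e_fret(cell, CAL), rel=1e-12)

    def test_nonpositive_denominator_yields_nan(self):
        cell = SingleCellIntensities(I_DD=0.0, I_DA=-10.0, I_AA=0.0)
        with pytest.warns(UserWarning):
            assert np.isnan(e_fret(cell, CAL))


class TestGFactor:
    def test_direct_arithmetic(self):
        cal = EFretCalibration(a=0.0, d=0.0, G=1.0)  # a = d = 0 here
        pre = SingleCellIntensities(I_DD=100.0, I_DA=100.0, I_AA=100.0)
        post = SingleCellIntensities(I_DD=150.0, I_DA=0.0, I_AA=1.0)
        assert g_factor(pre, post, 0.0, 0.0) == pytest.approx(2.0)

    def test_no_dequenching_raises(self):
        pre = SingleCellIntensities(I_DD=100.0, I_DA=100.0, I_AA=100.0)
        post = SingleCellIntensities(I_DD=100.0, I_DA=100.0, I_AA=1.0)
        with pytest.raises(CalibrationError):
            g_factor(pre, post, 0.0, 0.0)

    def test_population_round_trip(self):
        pop, _, _ = gen_single_cell_population(
            0.11, CAL, n_cells=2000, noise=NoiseSpec(intensity_cv=0.02, seed=13)
        )
        post = SingleCellIntensities(
            I_DD=pop.I_DD_post, I_DA=pop.I_DA_post, I_AA=pop.I_AA_post
        )
        assert g_factor(pop, post, CAL.a, CAL.d) == pytest.approx(CAL.G, rel=0.01)

    def test_incomplete_bleach_warns(self):
        pre = SingleCellIntensities(I_DD=100.0, I_DA=100.0, I_AA=100.0)
        post = SingleCellIntensities(I_DD=150.0, I_DA=0.0, I_AA=90.0)
        with pytest.warns(UserWarning):
            g_factor(pre, post, 0.0, 0.0)


class TestCorrectIntensities:
    def test_identity_when_zero(self):
        raw = SingleCellIntensities(I_DD=110.0, I_DA=120.0, I_AA=130.0)
        out = correct_intensities(raw, 0.0, 0.0)
        assert out.I_DD == 110.0 and out.I_DA == 120.0 and out.I_AA == 130.0

    def test_subtraction(self):
        raw = SingleCellIntensities(I_DD=110.0, I_DA=110.0, I_AA=110.0)
        out = correct_intensities(raw, 5.0, 5.0)
        assert out.I_DD == 100.0

    def test_not_idempotent(self):
        raw = SingleCellIntensities(I_DD=110.0, I_DA=110.0, I_AA=110.0)
        once = correct_intensities(raw, 5.0, 5.0)
        twice = correct_intensities(once, 5.0, 5.0)
        assert twice.I_DD != once.I_DD

    def test_negative_values_kept_and_flagged(self):
        raw = SingleCellIntensities(I_DD=3.0, I_DA=10.0, I_AA=10.0)
        out = correct_intensities(raw, 2.0, 2.0)
        assert out.I_DD == pytest.approx(-1.0)
        assert out.has_negative
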