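"""Patlak, Logan, MLAIR linearizations, SUV, and parametric maps."""
import numpy as np
import pytest

import medastac as m
from medastac.graphical import cumulative_integral, frame_cumulative
from medastac.simulate import add_noise, alpha_for_cv


KI = lambda p: p.K1 * p.k3 / (p.k2 + p.k3)


class TestCumulativeIntegral:
    def test_constant_and_ramp(self):
        t = np.linspace(0, 10, 11)
        assert cumulative_integral(np.ones(11), t)[-1] == pytest.approx(10.0)
        assert cumulative_integral(t, t)[-1] == pytest.approx(50.0)

    def test_exponential_closed_form(self):
        # trapezoid error ~ h^2/12 * int f'': 8e-4 at h=0.1, 3e-5 at h=0.02
        for h, tol in ((0.1, 1e-3), (0.02, 1e-4)):
            t = np.arange(0.0, 10.0001, h)
            cum = cumulative_integral(np.exp(-t), t)
            assert cum[-1] == pytest.approx(1 - np.exp(-10), abs=tol)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            cumulative_integral([1, 2], [5.0, 1.0])

    def test_frame_cumulative_consistency(self, schedule):
        tac = m.TimeActivityCurve(schedule, np.ones(schedule.n_frames))
        cum = frame_cumulative(tac)
        # constant curve: integral to each midpoint equals the midpoint time
        assert np.allclose(cum, schedule.midpoints)


class TestPatlak:
    def test_noiseless_exactness(self, inp, schedule):
        p = m.KineticParams(K1=0.25, k2=0.18, k3=0.15, VB=0.0)
        tac = m.model_tissue_curve("2T3k", p, inp, schedule)
        res = m.patlak(tac, inp, tstar=20.0)
        assert res.estimate == pytest.approx(KI(p), rel=0.01)
        assert res.r2 > 0.9999

    def test_no_trapping_gives_zero_slope(self, inp, schedule):
        p = m.KineticParams(K1=0.3, k2=0.3, VB=0.0)
        tac = m.model_tissue_curve("1T2k", p, inp, schedule)
        res = m.patlak(tac, inp, tstar=30.0)
        assert abs(res.estimate) < 2e-3

    def test_late_tstar_window_bookkeeping(self, inp, schedule):
        p = m.KineticParams(K1=0.25, k2=0.18, k3=0.15, VB=0.0)
        tac = m.model_tissue_curve("2T3k", p, inp, schedule)
        # the two last 600-s frames have midpoints 45.17 and 55.17 min
        assert int(np.sum(schedule.midpoints >= 44.0)) == 2
        res = m.patlak(tac, inp, tstar=44.0)
        assert res.n_points == 2 and res.low_confidence
        with pytest.raises(ValueError):  # only one midpoint at or past 55 min
            m.patlak(tac, inp, tstar=55.0)


class TestLogan:
    def test_one_tissue_volume_of_distribution(self, inp, schedule):
        p = m.KineticParams(K1=0.4, k2=0.5, VB=0.0)
        tac = m.model_tissue_curve("1T2k", p, inp, schedule)
        res = m.logan(tac, inp, tstar=20.0)
        assert res.estimate == pytest.approx(0.8, rel=0.01)
        assert not res.diverging

    def test_reversible_two_tissue(self, inp, schedule):
        p = m.KineticParams(K1=0.2, k2=0.1, k3=0.05, k4=0.1, VB=0.0)
        tac = m.model_tissue_curve("2T4k", p, inp, schedule)
        vt = (p.K1 / p.k2) * (1 + p.k3 / p.k4)
        assert m.logan(tac, inp, tstar=20.0).estimate == pytest.approx(vt, rel=0.02)

    def test_irreversible_truth_diverges(self, inp, schedule):
        p = m.KineticParams(K1=0.25, k2=0.18, k3=0.15, VB=0.0)
        tac = m.model_tissue_curve("2T3k", p, inp, schedule)
        assert m.logan(tac, inp, tstar=10.0).diverging


class TestMlair:
    def test_noiseless_exactness_and_agreement(self, inp, schedule):
        p = m.KineticParams(K1=0.25, k2=0.18, k3=0.15, VB=0.0)
        tac = m.model_tissue_curve("2T3k", p, inp, schedule)
        k1 = m.mlair1(tac, inp)
        k2 = m.mlair2(tac, inp)
        assert k1.estimate == pytest.approx(KI(p), rel=0.005)
        assert k2.estimate == pytest.approx(KI(p), rel=0.005)
        assert k1.estimate == pytest.approx(k2.estimate, rel=0.001)

    def test_blood_volume_coefficient(self, inp, schedule):
        p = m.KineticParams(K1=0.25, k2=0.18, k3=0.15, VB=0.05)
        tac = m.model_tissue_curve("2T3k", p, inp, schedule)
        res = m.mlair1(tac, inp)
        assert res.coefficients[0] == pytest.approx(0.05, abs=0.005)  # P1 = V_B
        # apparent Ki absorbs (1 - V_B); dividing it out restores the truth
        assert res.estimate == pytest.approx((1 - 0.05) * KI(p), rel=0.01)
        assert m.mlair1(tac, inp, vb=0.05).estimate == pytest.approx(KI(p), rel=0.01)

    def test_degenerate_tac_rejected(self, inp, schedule):
        zero = m.TimeActivityCurve(schedule, np.zeros(schedule.n_frames))
        with pytest.raises((np.linalg.LinAlgError, ZeroDivisionError, ValueError)):
            m.mlair1(zero, inp)

    def test_voxel_noise_robustness_ordering(self, inp, schedule):
        """MLAIR2's direct-coefficient Ki is far more stable than the MLAIR1
        coefficient ratio at high (voxel-like) noise, while Patlak keeps a
        systematic negative (equilibration) bias."""
        p = m.KineticParams(K1=0.25, k2=0.18, k3=0.15, VB=0.0)
        clean = m.model_tissue_curve("2T3k", p, inp, schedule)
        alpha = alpha_for_cv(clean, 0.30)
        k_pat, k_m1, k_m2 = [], [], []
        for i in range(250):
            noisy = add_noise(clean, alpha, seed=i)
            try:
                k_pat.append(m.patlak(noisy, inp, 20.0).estimate)
                k_m1.append(m.mlair1(noisy, inp).estimate)
                k_m2.append(m.mlair2(noisy, inp).estimate)
            except (ValueError, ZeroDivisionError, np.linalg.LinAlgError):
                continue
        k_pat, k_m1, k_m2 = map(np.asarray, (k_pat, k_m1, k_m2))
        assert np.var(k_m2) < np.var(k_m1)
        assert np.mean(k_pat) < KI(p)  # Patlak under-estimates (transient term)


class TestSuv:
    def test_arithmetic(self, schedule):
        tac = m.TimeActivityCurve(schedule, np.full(schedule.n_frames, 3.0))
        meta = m.SubjectMeta(210.0, 70.0)
        with pytest.warns(UserWarning, match="not aligned"):
            v = m.suv(tac, (40.0, 50.0), meta)
        assert v.suv == pytest.approx(1.0)
        half = m.suv(tac, (40.0, 50.0), m.SubjectMeta(420.0, 70.0))
        assert half.suv == pytest.approx(0.5)

    def test_window_overlaps_two_late_frames(self, schedule):
        overlap = np.minimum(schedule.frame_end, 50.0) - np.maximum(schedule.frame_start, 40.0)
        assert int(np.sum(overlap > 0)) == 2

    def test_invariant_to_frame_subdivision(self):
        coarse = m.parse_frame_schedule("1x600,1x600")
        fine = m.parse_frame_schedule("4x300")
        meta = m.SubjectMeta(200.0, 75.0)
        tc = m.TimeActivityCurve(coarse, np.array([2.0, 4.0]))
        tf = m.TimeActivityCurve(fine, np.array([2.0, 2.0, 4.0, 4.0]))
        assert m.suv(tc, (0.0, 20.0), meta).suv == pytest.approx(m.suv(tf, (0.0, 20.0), meta).suv)

    def test_interval_outside_scan_rejected(self, schedule):
        tac = m.TimeActivityCurve(schedule, np.ones(schedule.n_frames))
        with pytest.raises(ValueError):
            m.suv(tac, (55.0, 70.0), m.SubjectMeta(200.0, 75.0))


class TestParametricMap:
    def test_uniform_volume_and_nan_passthrough(self, inp, schedule):
        p = m.KineticParams(K1=0.25, k2=0.18, k3=0.15, VB=0.02)
        tac = m.model_tissue_curve("2T3k", p, inp, schedule)
        vol = np.tile(tac.activity, (2, 2, 1))
        vol[1, 1, :] = np.nan  # masked voxel
        out = m.parametric_map("mlair2", vol, schedule, inp)
        ref = m.mlair2(tac, inp).estimate
        assert np.allclose(out[0, 0], ref) and np.allclose(out[0, 1], ref)
        assert np.isnan(out[1, 1])

    def test_two_tissue_phantom_ordering(self, inp, schedule):
        wm = m.model_tissue_curve("2T3k", m.KineticParams(0.25, 0.18, 0.15, VB=0.02), inp, schedule)
        gm = m.model_tissue_curve("2T3k", m.KineticParams(0.40, 0.50, 0.095, VB=0.05), inp, schedule)
        vol = np.stack([np.tile(wm.activity, (2, 1)), np.tile(gm.activity, (2, 1))])
        out = m.parametric_map("mlair2", vol, schedule, inp)
        assert out[0].mean() > out[1].mean()  # white matter traps more tracer

    def test_unsupported_method(self, inp, schedule):
        vol = np.zeros((1, schedule.n_frames))
        with pytest.raises(ValueError, match="unsupported"):
            m.parametric_map("logan", vol, schedule, inp)
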