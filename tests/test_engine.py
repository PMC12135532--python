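import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fosfopk.engine import (
    DoseEvent,
    KRTWindow,
    analytic_twocpt,
    build_segments,
    regimen_events,
    simulate_population,
    simulate_profile,
)
from fosfopk.model import IndividualParams


def _params(cl=1.6, vc=23.1, vp=15.4, q=12.0, slope=0.0):
    return IndividualParams(
        cl_body=cl, v_c=vc, v_p0=vp, vp_slope_per_h=slope, q=q,
        theta_dial=2.0, theta_qd=0.587,
    )


TID = [DoseEvent(8.0 * i, 4000.0, 1.0) for i in range(6)]
PIKRT = [KRTWindow(24.0, 32.0, 250.0)]


class TestSegments:
    def test_single_infusion(self):
        segs = build_segments([DoseEvent(0, 1000, 1.0)], [], 8.0)
        assert [(s.t0, s.t1) for s in segs] == [(0.0, 1.0), (1.0, 8.0)]
        assert segs[0].rate == 1000.0 and segs[1].rate == 0.0

    def test_breakpoints_enumerate_all_events(self):
        # brute-force breakpoint enumeration: dose starts/stops within the
        # horizon plus KRT start/stop plus the interval ends
        expected = {0.0, 48.0}
        for d in TID:
            expected |= {d.start_time, d.start_time + d.duration}
        expected |= {24.0, 32.0}
        segs = build_segments(TID, PIKRT, 48.0)
        breakpoints = {segs[0].t0} | {s.t1 for s in segs}
        assert breakpoints == expected
        assert len(segs) == len(expected) - 1
        # segments tile the horizon exactly
        assert segs[0].t0 == 0.0 and segs[-1].t1 == 48.0
        assert all(a.t1 == b.t0 for a, b in zip(segs, segs[1:]))

    def test_krt_half_open(self):
        segs = build_segments([], PIKRT, 48.0)
        state = {(s.t0, s.t1): s.krt_active for s in segs}
        assert state[(24.0, 32.0)] is True
        assert state[(32.0, 48.0)] is False

    def test_empty_regimen(self):
        segs = build_segments([], [], 10.0)
        assert len(segs) == 1 and segs[0].rate == 0.0

    def test_overlapping_krt_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            build_segments([], [KRTWindow(0, 10, 42), KRTWindow(5, 15, 42)], 20.0)


class TestAnalyticOracle:
    def test_auc_equals_dose_over_cl(self):
        # single 4000 mg dose, total CL 2.0 L/h: AUC(0->inf) = 2000 mg*h/L
        p = _params(cl=2.0)
        grid = np.arange(0.0, 400.0, 0.05)
        prof = analytic_twocpt(p, [DoseEvent(0, 4000, 1.0)], [], grid)
        auc = np.trapezoid(prof.conc_central, prof.times)
        assert auc == pytest.approx(4000.0 / 2.0, rel=2e-3)

    def test_linearity_in_dose(self):
        grid = np.arange(0.0, 48.0, 0.5)
        p = _params()
        c1 = analytic_twocpt(p, [DoseEvent(0, 1000, 0.5)], [], grid).conc_central
        c2 = analytic_twocpt(p, [DoseEvent(0, 2000, 0.5)], [], grid).conc_central
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-10)

    def test_bolus_limit_matches_twocpt_formula(self):
        # a very short infusion approaches the standard bolus solution
        cl, q, vc, vp = 2.0, 12.0, 23.1, 15.4
        p = _params(cl=cl)
        grid = np.array([2.0, 6.0, 12.0, 24.0])
        prof = analytic_twocpt(p, [DoseEvent(0, 1000, 1e-7)], [], grid)
        k10, k12, k21 = cl / vc, q / vc, q / vp
        s = k10 + k12 + k21
        disc = np.sqrt(s * s - 4 * k10 * k21)
        alpha, beta = (s + disc) / 2, (s - disc) / 2
        A = 1000.0 / vc * (alpha - k21) / (alpha - beta)
        B = 1000.0 / vc * (k21 - beta) / (alpha - beta)
        expected = A * np.exp(-alpha * grid) + B * np.exp(-beta * grid)
        np.testing.assert_allclose(prof.conc_central, expected, rtol=1e-5)

    def test_rejects_growing_vp(self):
        with pytest.raises(ValueError):
            analytic_twocpt(_params(slope=0.01), TID, [], np.arange(0, 48, 0.5))


class TestSimulateProfile:
    def test_matches_analytic_oracle(self):
        grid = np.arange(0.0, 48.0001, 0.1)
        p = _params()
        ode = simulate_profile(p, TID, PIKRT, grid)
        ana = analytic_twocpt(p, TID, PIKRT, grid)
        nz = ana.conc_central > 1.0
        rel = np.abs(ode.conc_central[nz] - ana.conc_central[nz]) / ana.conc_central[nz]
        assert rel.max() < 1e-3

    @given(
        cl=st.floats(0.0, 10.0),
        vc=st.floats(5.0, 60.0),
        vp=st.floats(5.0, 60.0),
        q=st.floats(2.0, 30.0),
        dose=st.floats(500.0, 10000.0),
    )
    @settings(max_examples=15, deadline=None)
    def test_oracle_equivalence_random_battery(self, cl, vc, vp, q, dose):
        p = _params(cl=cl, vc=vc, vp=vp, q=q)
        grid = np.arange(0.0, 24.0001, 0.25)
        reg = [DoseEvent(0.0, dose, 0.75), DoseEvent(8.0, dose, 0.75)]
        ode = simulate_profile(p, reg, [], grid)
        ana = analytic_twocpt(p, reg, [], grid)
        scale = ana.conc_central.max()
        assert np.abs(ode.conc_central - ana.conc_central).max() / scale < 1e-3

    def test_mass_balance(self, typical_params):
        # total drug eliminated equals total infused: integral of CL*C dt
        grid = np.arange(0.0, 1000.0001, 0.1)
        reg = [DoseEvent(0, 4000, 1.0)]
        prof = simulate_profile(typical_params, reg, [], grid)
        eliminated = np.trapezoid(typical_params.cl_body * prof.conc_central, prof.times)
        assert eliminated == pytest.approx(4000.0, rel=5e-3)

    def test_no_elimination_conserves_mass(self):
        # anuric, no dialysis: central + peripheral equals cumulative infusion
        p = _params(cl=0.0, slope=0.042)
        grid = np.arange(0.0, 30.0001, 0.5)
        prof = simulate_profile(p, TID, [], grid)
        total = prof.amounts.sum(axis=1)
        infused = np.array(
            [sum(min(max(t - d.start_time, 0), d.duration) * d.rate for d in TID)
             for t in prof.times]
        )
        np.testing.assert_allclose(total, infused, rtol=1e-6, atol=1e-6)

    def test_superposition(self):
        grid = np.arange(0.0, 24.0001, 0.25)
        p = _params()
        both = simulate_profile(p, TID[:2], [], grid).conc_central
        one = simulate_profile(p, [TID[0]], [], grid).conc_central
        two = simulate_profile(p, [TID[1]], [], grid).conc_central
        np.testing.assert_allclose(both, one + two, rtol=1e-6, atol=1e-8)


class TestSteadyState:
    def test_auc_over_interval_equals_dose_over_cl(self):
        # >= 10 half-lives in: AUC over one dosing interval ~ dose / CL
        p = _params(cl=2.0, vc=20.0, vp=10.0, q=12.0)
        grid = np.arange(0.0, 400.0001, 0.05)
        reg = regimen_events(4000.0, 8.0, 1.0, 400.0)
        prof = analytic_twocpt(p, reg, [], grid)
        sel = (prof.times >= 384.0) & (prof.times <= 392.0)
        auc = np.trapezoid(prof.conc_central[sel], prof.times[sel])
        assert auc == pytest.approx(4000.0 / 2.0, rel=5e-3)


class TestSimulatePopulation:
    def _clkrt(self, qd):
        return 2.0 * (qd / 42.0) ** 0.587

    def test_matches_analytic_constant_vp(self):
        grid = np.arange(0.0, 48.0001, 0.1)
        p = _params()
        conc = simulate_population(
            np.array([p.cl_body]), np.array([p.v_c]), np.array([p.v_p0]),
            np.array([0.0]), p.q, self._clkrt, TID, PIKRT, grid,
        )
        ana = analytic_twocpt(p, TID, PIKRT, grid).conc_central
        np.testing.assert_allclose(conc[0], ana, rtol=1e-9, atol=1e-9)

    def test_matches_ode_growing_vp(self):
        grid = np.arange(0.0, 48.0001, 0.1)
        p = _params(cl=0.0, slope=0.0007 * 60)
        conc = simulate_population(
            np.array([0.0]), np.array([p.v_c]), np.array([p.v_p0]),
            np.array([p.vp_slope_per_h]), p.q, self._clkrt, TID, PIKRT, grid,
        )
        ode = simulate_profile(p, TID, PIKRT, grid).conc_central
        nz = ode > 1.0
        assert (np.abs(conc[0][nz] - ode[nz]) / ode[nz]).max() < 1e-3

    def test_monotone_in_dialysis_clearance(self):
        grid = np.arange(0.0, 48.0001, 0.1)
        base = simulate_population(
            np.array([1.6]), np.array([23.1]), np.array([15.4]), np.array([0.0]),
            12.0, self._clkrt, TID, PIKRT, grid,
        )
        boosted = simulate_population(
            np.array([1.6]), np.array([23.1]), np.array([15.4]), np.array([0.0]),
            12.0, lambda qd: 2 * self._clkrt(qd), TID, PIKRT, grid,
        )
        auc_base = np.trapezoid(base[0], grid)
        auc_boost = np.trapezoid(boosted[0], grid)
        assert auc_boost < auc_base
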