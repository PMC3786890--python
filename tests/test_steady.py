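"""Closed-form steady states, decay lengths, binding-rate inversion, cycle times."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import kinesim as ks
from kinesim.steady import dispersion_roots


def bisect_decay_length(v, D, k_on, k_off, lo=1e-8, hi=1e8, tol=1e-12):
    """Independent oracle: bisection on f(y) = D·v·y² + D·k_off·y − k_on·v."""
    f = lambda y: D * v * y * y + D * k_off * y - k_on * v
    assert f(lo) < 0 < f(hi)
    while hi - lo > tol * hi:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 1.0 / (0.5 * (lo + hi))


class TestDecayLength:
    def test_paper_parameters_give_3_76_um(self, paper_params):
        lam = ks.decay_length(paper_params)
        oracle = bisect_decay_length(0.78, 4.08, 1.22, 0.67)
        assert lam == pytest.approx(oracle, rel=1e-9)
        assert lam == pytest.approx(3.7617, rel=1e-4)

    def test_unit_parameters_reduce_to_unity(self):
        # with k_off = 0 the dispersion relation collapses to y² = k_on/D
        p = ks.MotorParams(v=1, D=1, k_on=1, k_off=0)
        assert ks.decay_length(p) == pytest.approx(1.0, rel=1e-12)

    def test_hybrid2_length_is_sqrt_D_over_kon(self, paper_params):
        lam = ks.decay_length(paper_params, ks.HYBRID2)
        assert lam == pytest.approx(math.sqrt(4.08 / 1.22), rel=1e-12)
        assert lam == pytest.approx(1.829, abs=5e-4)

    def test_no_binding_means_no_accumulation(self, paper_params):
        assert math.isinf(ks.decay_length(paper_params.replace(k_on=0.0)))

    def test_nonpositive_parameters_rejected(self, paper_params):
        with pytest.raises(ValueError):
            ks.decay_length(ks.MotorParams(v=0, D=4, k_on=1, k_off=1))
        with pytest.raises(ValueError):
            ks.MotorParams(v=-1, D=4, k_on=1, k_off=1)


class TestBindingRateInversion:
    def test_paper_lambda_yields_1_22(self, paper_params):
        lam = ks.decay_length(paper_params)
        k_on = ks.infer_binding_rate(lam, v=0.78, D=4.08, k_off=0.67)
        assert k_on == pytest.approx(1.22, rel=1e-9)

    def test_unit_case(self):
        assert ks.infer_binding_rate(1.0, v=1, D=1, k_off=0) == pytest.approx(1.0)

    @given(
        v=st.floats(0.1, 10.0),
        D=st.floats(0.1, 10.0),
        k_on=st.floats(0.05, 5.0),
        k_off=st.floats(0.0, 5.0),
    )
    def test_round_trip_identity(self, v, D, k_on, k_off):
        p = ks.MotorParams(v=v, D=D, k_on=k_on, k_off=k_off)
        lam = ks.decay_length(p)
        assert ks.infer_binding_rate(lam, v=v, D=D, k_off=k_off) == pytest.approx(
            k_on, rel=1e-9
        )

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            ks.infer_binding_rate(-1.0, v=1, D=1, k_off=0)


class TestSteadyStateClosedForms:
    def test_lbb_total_density_is_exponential_with_lambda(self, paper_params, geom30):
        ss = ks.steady_state(ks.LOOSE_BUCKET_BRIGADE, paper_params, geom30)
        lam = ks.decay_length(paper_params)
        assert ss.profile_family == "exponential"
        assert ss.decay_length == pytest.approx(lam)
        L = geom30.L
        ratio = ss.c_tot(np.array(L)) / ss.c_tot(np.array(L - lam))
        assert ratio == pytest.approx(math.e, rel=1e-6)

    def test_lbb_bound_fraction_matches_flux_balance(self, paper_params, geom30):
        # interior bound fraction D·y/(D·y+v): local two-state balance
        # including the advective loss term (k_on c_f = (k_off + v·y)·c_b)
        ss = ks.steady_state(ks.LOOSE_BUCKET_BRIGADE, paper_params, geom30)
        y = 1.0 / ks.decay_length(paper_params)
        expected = paper_params.D * y / (paper_params.D * y + paper_params.v)
        assert ss.bound_fraction == pytest.approx(expected, rel=1e-2)

    @pytest.mark.parametrize(
        "variant",
        [ks.DILIGENT_WORKER, ks.LOOSE_BUCKET_BRIGADE, ks.HYBRID1, ks.HYBRID2,
         ks.ModelVariant("hybrid1", True, True, False)],
        ids=lambda v: v.name + ("_reattach" if v.reattach_in_transit and v.name == "hybrid1" else ""),
    )
    def test_densities_nonnegative(self, variant, paper_params, geom30):
        ss = ks.steady_state(variant, paper_params, geom30)
        x = np.linspace(0, geom30.L, 500)
        for f in (ss.c_bound, ss.c_free, ss.c_inert):
            assert np.all(f(x) >= -1e-12)

    def test_dw_bound_uniform_free_linear(self, paper_params, geom30):
        ss = ks.steady_state(ks.DILIGENT_WORKER, paper_params, geom30, J=2.0)
        x = np.linspace(0, geom30.L, 100)
        assert np.allclose(ss.c_bound(x), 2.0 / paper_params.v)
        diffusing = ss.c_free(x) + ss.c_inert(x)
        assert np.allclose(diffusing, 2.0 * x / paper_params.D)

    def test_dw_and_reattaching_h1_totals_non_decreasing(self, paper_params, geom30):
        # the Diligent Worker total grows everywhere; the reattaching Hybrid 1
        # shares the LBB's ~1 µm depleted layer at the absorbing soma and is
        # non-decreasing beyond it
        x = np.linspace(0, geom30.L, 400)
        ss = ks.steady_state(ks.DILIGENT_WORKER, paper_params, geom30)
        assert ss.profile_family == "linear"
        assert np.all(np.diff(ss.c_tot(x)) >= -1e-10)
        h1r = ks.ModelVariant("hybrid1", True, True, False)
        ss = ks.steady_state(h1r, paper_params, geom30)
        assert ss.profile_family == "linear"
        x_distal = x[x >= 5.0]
        assert np.all(np.diff(ss.c_tot(x_distal)) >= -1e-10)

    @pytest.mark.parametrize("variant", [ks.LOOSE_BUCKET_BRIGADE, ks.HYBRID2], ids=lambda v: v.name)
    def test_exponential_totals_log_linear_distally(self, variant, paper_params, geom30):
        # the exact solutions carry a subdominant soma boundary-layer mode;
        # beyond it the log-density is linear to double precision
        ss = ks.steady_state(variant, paper_params, geom30)
        x = np.linspace(0.6 * geom30.L, geom30.L, 200)
        logc = np.log(ss.c_tot(x))
        assert np.all(np.diff(logc) > 0)  # strictly increasing
        second = np.diff(logc, 2)
        assert np.max(np.abs(second)) < 1e-8
        slope = (logc[-1] - logc[0]) / (x[-1] - x[0])
        assert slope == pytest.approx(1.0 / ss.decay_length, rel=1e-6)

    def test_degenerate_inputs_give_flat_profile(self, paper_params, geom30):
        for ss in (
            ks.steady_state(ks.DILIGENT_WORKER, paper_params, geom30, J=0.0),
            ks.steady_state(ks.DILIGENT_WORKER, paper_params.replace(v=0.0), geom30),
        ):
            assert ss.profile_family == "flat"
            assert ss.decay_length is None
            x = np.linspace(0, 30, 50)
            assert np.allclose(ss.c_bound(x), 0.0)
            assert np.ptp(ss.c_free(x)) == 0.0


class TestCycleTimes:
    def test_diligent_worker_at_65_um_takes_about_ten_minutes(self, paper_params):
        t = ks.cycle_time(ks.DILIGENT_WORKER, paper_params, ks.Geometry1D(65.0))
        assert t == pytest.approx(65 / 0.78 + 65**2 / (2 * 4.08), rel=1e-12)
        assert t == pytest.approx(601.1, abs=0.1)
        assert 9.0 < t / 60.0 < 11.0

    def test_lbb_cycle_constant_in_length(self, paper_params):
        ts = [
            ks.cycle_time(ks.LOOSE_BUCKET_BRIGADE, paper_params, ks.Geometry1D(L))
            for L in (5.0, 20.0, 80.0)
        ]
        assert ts[0] == pytest.approx(1 / 0.67 + 1 / 1.22, rel=1e-12)
        assert ts[0] == ts[1] == ts[2]
        assert ts[0] == pytest.approx(2.312, abs=5e-4)

    def test_dw_cycle_increasing_and_diffusion_dominated(self, paper_params):
        Ls = np.array([5.0, 10.0, 20.0, 40.0, 80.0, 160.0])
        ts = np.array([
            ks.cycle_time(ks.DILIGENT_WORKER, paper_params, ks.Geometry1D(L)) for L in Ls
        ])
        assert np.all(np.diff(ts) > 0)
        L_big = 160.0
        assert L_big**2 / (2 * paper_params.D) > 0.9 * ks.cycle_time(
            ks.DILIGENT_WORKER, paper_params, ks.Geometry1D(L_big)
        )

    def test_short_process_diffusion_does_not_limit_recycling(self, paper_params):
        # at L = 10 µm the diffusive return (~12.3 s) is comparable to the run
        L = 10.0
        t_diff = L**2 / (2 * paper_params.D)
        t_run = L / paper_params.v
        assert t_diff == pytest.approx(12.25, abs=0.01)
        assert t_diff / t_run < 2.0

    def test_short_length_limit(self, paper_params):
        assert ks.cycle_time(ks.DILIGENT_WORKER, paper_params, ks.Geometry1D(1e-9)) < 1e-6

    def test_invalid_inputs(self, paper_params):
        with pytest.raises(ValueError):
            ks.Geometry1D(0.0)
        with pytest.raises(ValueError):
            ks.cycle_time(ks.HYBRID2, paper_params, ks.Geometry1D(10.0))
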