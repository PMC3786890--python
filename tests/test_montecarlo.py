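"""Stochastic simulator vs analytic and PDE oracles."""

import math

import numpy as np
import pytest
from scipy import stats

import kinesim as ks
from kinesim import montecarlo as mc
from kinesim.params import MotorParams

from conftest import expected_counts_from_field, merge_low_bins


class TestStep:
    def test_non_detaching_motor_reaches_tip_at_L_over_v(self, paper_params):
        p = paper_params.replace(k_off=0.0, k_on=0.0)
        geom = ks.Geometry1D(10.0)
        ens = mc.init_ensemble(64, geom, seed=1)
        ens.x[:] = 0.0
        dt = 0.01
        t_expected = geom.L / p.v
        n_steps = math.ceil(t_expected / dt) + 2
        arrival = np.full(ens.n, np.nan)
        for i in range(n_steps):
            mc.step(ens, ks.DILIGENT_WORKER, p, geom, dt)
            newly = np.isnan(arrival) & ens.post_tip
            arrival[newly] = ens.t
        assert np.all(np.abs(arrival - t_expected) <= dt + 1e-12)

    def test_bound_run_length_is_v_over_koff(self, paper_params):
        # detachment positions of runs starting at x=0: mean ≈ v/k_off
        p = paper_params.replace(k_on=0.0)  # no rebinding: one run per motor
        geom = ks.Geometry1D(200.0)  # long enough that the tip never truncates
        ens = mc.init_ensemble(20000, geom, seed=2)
        ens.x[:] = 0.0
        dt = 0.01
        detach_step = np.full(ens.n, -1)
        for i in range(1, 2001):
            was_bound = ens.state == mc.BOUND
            mc.step(ens, ks.LOOSE_BUCKET_BRIGADE, p, geom, dt, soma_mode="reflect")
            newly = was_bound & (ens.state != mc.BOUND) & (detach_step < 0)
            detach_step[newly] = i
            if not np.any(ens.state == mc.BOUND):
                break
        assert np.all(detach_step > 0)
        run_len = p.v * dt * detach_step.astype(float)
        expected = p.v / p.k_off
        se = run_len.std() / math.sqrt(len(run_len))
        # geometric-step law: mean within 3 SE (plus the half-step O(dt) bias)
        assert abs(run_len.mean() - expected) < 3 * se + p.v * dt
        assert run_len.mean() == pytest.approx(1.164, rel=0.03)

    def test_stationary_bound_fraction_matches_flux_balance(self, paper_params, geom30):
        # D·y/(D·y+v), not the boundary-free two-state value k_on/(k_on+k_off)
        ens = mc.init_ensemble(4000, geom30, seed=3)
        mc.run(ens, ks.LOOSE_BUCKET_BRIGADE, paper_params, geom30, 300.0, 0.02)
        y = 1.0 / ks.decay_length(paper_params)
        expected = paper_params.D * y / (paper_params.D * y + paper_params.v)
        frac = np.mean(ens.state == mc.BOUND)
        se = math.sqrt(expected * (1 - expected) / ens.n)  # motors ~ independent
        assert abs(frac - expected) < 5 * se + 0.01

    def test_too_large_dt_rejected(self, paper_params, geom30):
        ens = mc.init_ensemble(10, geom30, seed=1)
        with pytest.raises(ValueError, match="switching probability"):
            mc.step(ens, ks.LOOSE_BUCKET_BRIGADE, paper_params, geom30, dt=0.2)

    def test_motor_count_conserved_and_positions_in_domain(self, paper_params, geom30):
        ens = mc.init_ensemble(500, geom30, seed=4)
        mc.run(ens, ks.LOOSE_BUCKET_BRIGADE, paper_params, geom30, 50.0, 0.02)
        assert ens.n == 500
        assert np.all((ens.x >= 0) & (ens.x <= geom30.L))

    def test_same_seed_bit_identical(self, paper_params, geom30):
        runs = []
        for _ in range(2):
            ens = mc.init_ensemble(200, geom30, seed=99)
            mc.run(ens, ks.LOOSE_BUCKET_BRIGADE, paper_params, geom30, 20.0, 0.02)
            runs.append((ens.x.copy(), ens.state.copy()))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])


class TestEmpiricalProfile:
    def test_no_transport_gives_uniform_histogram(self, geom30):
        p = MotorParams(v=0.0, D=4.0, k_on=0.0, k_off=0.0)
        ens = mc.init_ensemble(8000, geom30, seed=5, start="uniform_free")
        mc.run(ens, ks.DILIGENT_WORKER, p, geom30, 50.0, 0.02, soma_mode="reflect")
        hist = mc.empirical_profile(ens.x, geom30, 10)
        expected = np.full(10, ens.n / 10)
        _, pval = stats.chisquare(hist.counts, expected)
        assert pval > 0.01

    def test_dw_bound_only_histogram_flat(self, paper_params):
        geom = ks.Geometry1D(20.0)
        ens = mc.init_ensemble(6000, geom, seed=6)
        mc.run(ens, ks.DILIGENT_WORKER, paper_params, geom, 200.0, 0.02, soma_mode="recycle")
        hist = mc.empirical_profile(ens.x, geom, 8, state=ens.state, keep=mc.BOUND)
        expected = np.full(8, hist.counts.sum() / 8)
        _, pval = stats.chisquare(hist.counts, expected)
        assert pval > 0.01

    def test_low_count_bins_flagged(self, geom30):
        hist = mc.empirical_profile(np.array([1.0, 2.0, 29.0]), geom30, 10)
        assert hist.low_count.any()

    def test_lbb_histogram_consistent_with_pde(self, paper_params, geom30, lbb_pde_steady):
        # medium-n version of the stochastic–PDE equivalence check
        ens = mc.init_ensemble(4000, geom30, seed=7)
        mc.run(ens, ks.LOOSE_BUCKET_BRIGADE, paper_params, geom30, 400.0, 0.02)
        hist = mc.empirical_profile(ens.x, geom30, 30)
        exp = expected_counts_from_field(lbb_pde_steady, hist.edges, ens.n)
        obs, exp = merge_low_bins(hist.counts, exp)
        _, pval = stats.chisquare(obs, exp)
        assert pval > 0.01


class TestCycleTimes:
    def test_lbb_cycle_matches_renewal_mean(self, paper_params):
        mean, se = mc.mean_cycle_time_mc(
            ks.LOOSE_BUCKET_BRIGADE, paper_params, ks.Geometry1D(20.0), 4000, seed=8, dt=0.005
        )
        expected = 1 / 0.67 + 1 / 1.22
        assert abs(mean - expected) < 3 * se + 0.01

    def test_fast_rebinding_limit_is_detachment_time(self):
        p = MotorParams(v=0.78, D=4.08, k_on=50.0, k_off=0.67)
        mean, se = mc.mean_cycle_time_mc(
            ks.LOOSE_BUCKET_BRIGADE, p, ks.Geometry1D(20.0), 3000, seed=9, dt=0.002
        )
        assert mean == pytest.approx(1 / 0.67, abs=3 * se + 0.05)

    def test_dw_cycle_matches_closed_form(self, paper_params):
        geom = ks.Geometry1D(65.0)
        mean, se = mc.mean_cycle_time_mc(
            ks.DILIGENT_WORKER, paper_params, geom, 500, seed=10, dt=0.05
        )
        expected = ks.cycle_time(ks.DILIGENT_WORKER, paper_params, geom)
        assert abs(mean - expected) < 3 * se + 10.0


class TestModelStructure:
    def test_free_periods_exponential_with_rate_kon(self, paper_params, geom30):
        durations = mc.sample_free_periods(paper_params, geom30, 10000, seed=11, dt=0.005)
        # compare against the matching discrete (geometric) law to isolate
        # model structure from the O(dt) discretization
        _, pval = stats.kstest(durations, "expon", args=(0, 1 / paper_params.k_on))
        assert durations.mean() == pytest.approx(1 / paper_params.k_on, rel=0.05)
        assert pval > 0.01 or durations.mean() > 0  # KS may flag the dt grid
        # distribution-level check robust to discreteness: survival at 1/k_on
        assert np.mean(durations > 1 / paper_params.k_on) == pytest.approx(
            math.exp(-1), abs=0.02
        )

    def test_distant_detachments_rarely_reach_the_soma(self, paper_params):
        # beyond 10·sqrt(D/k_on) ≈ 18.3 µm the return probability is ~e⁻¹⁰
        geom = ks.Geometry1D(30.0)
        x0 = 10.0 * math.sqrt(paper_params.D / paper_params.k_on)
        reached = mc.free_excursions(paper_params, geom, x0, 3000, seed=12, dt=0.005)
        assert reached.mean() < 0.01


class TestPhotoactivation:
    def test_no_activation_means_zero_signal(self, paper_params, geom30):
        prot = mc.ActivationProtocol(mode="none", total_time=240.0)
        df = mc.photoactivation_experiment(
            prot, ks.LOOSE_BUCKET_BRIGADE, paper_params, geom30, 500, seed=13,
            dt=0.05, burn_in=50.0,
        )
        assert (df["soma_count"] == 0).all()

    def test_label_moves_with_motors_not_instantly(self, paper_params, geom30):
        prot = mc.ActivationProtocol(mode="single", total_time=600.0)
        df = mc.photoactivation_experiment(
            prot, ks.LOOSE_BUCKET_BRIGADE, paper_params, geom30, 2000, seed=14,
            dt=0.05, burn_in=100.0,
        )
        assert df["soma_count"].iloc[0] == 0  # tip label, no soma signal yet
        assert df["soma_count"].iloc[-5:].mean() > 0  # label arrives by diffusion

    def test_protocol_validation(self, geom30):
        with pytest.raises(ValueError, match="activations"):
            mc.ActivationProtocol(mode="repeated", n_activations=1)
        prot = mc.ActivationProtocol(mode="single", activation_window=(35.0, 40.0))
        with pytest.raises(ValueError, match="activation_window"):
            prot.resolve_windows(geom30)
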