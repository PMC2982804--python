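"""Steady-state summaries, homeostasis maps, perturbations, profiles."""

import numpy as np
import pytest

import mtlength as mt
from mtlength.analysis import (estimate_catastrophe_rate,
                               estimate_growth_velocity)


class TestSummarize:
    def test_constant_trajectory_is_degenerate(self):
        p = mt.make_params()
        traj = mt.CellTrajectory(times=np.arange(10.0),
                                 L_B_series=np.full(10, 22.0),
                                 n_B_series=np.full(10, 2), params=p)
        s = mt.summarize(traj, burn_in=0.0)
        assert s.mean_length == 44.0
        assert s.sd_length == 0.0
        assert s.cv_length == 0.0

    def test_empty_window_rejected(self):
        traj = mt.simulate(mt.make_params(seed=1), 10.0)
        with pytest.raises(ValueError, match="burn_in"):
            mt.summarize(traj, burn_in=100.0)

    def test_contact_count_is_about_two_at_defaults(self, long_default_summary):
        assert 1.4 < long_default_summary.mean_n_B < 2.5

    def test_reduced_cortical_catastrophe_inflates_variability(self):
        base = mt.summarize(mt.simulate(mt.make_params(seed=5), 3000.0), 500)
        low = mt.summarize(
            mt.simulate(mt.make_params(c_B=0.3, seed=6), 3000.0), 500)
        assert low.sd_length > 3 * base.sd_length


class TestHomeostasisMap:
    def test_single_cell_grid_reduces_to_summarize(self):
        p = mt.make_params(seed=8)
        hmap = mt.homeostasis_map([11], [8.0], p, duration=2000.0,
                                  burn_in=200.0)
        from mtlength.analysis import _seed_int

        traj = mt.simulate(p.replace(seed=_seed_int(p.seed, 0, 0)), 2000.0)
        s = mt.summarize(traj, 200.0)
        assert hmap.sd_length[0, 0] == pytest.approx(s.sd_length)
        assert hmap.mean_length[0, 0] == pytest.approx(s.mean_length)

    def test_grid_errors_are_annotated(self):
        with pytest.raises(ValueError, match=r"alpha=-1"):
            mt.homeostasis_map([11], [-1.0], mt.make_params(),
                               duration=2000.0, burn_in=200.0)

    def test_map_export_shape(self, tmp_path):
        hmap = mt.homeostasis_map([5, 11], [4.0, 8.0], mt.make_params(seed=9),
                                  duration=2000.0, burn_in=200.0)
        assert hmap.sd_length.shape == (2, 2)
        assert np.all(np.isfinite(hmap.sd_length))
        assert np.all(hmap.sd_length >= 0)
        out = tmp_path / "map.csv"
        hmap.to_csv(out)
        assert out.read_text().startswith("N_m")


class TestPerturbation:
    def test_empty_factor_map_is_identity(self):
        p = mt.make_params(seed=4)
        a = mt.perturb_parameter(p, 100.0, {}, 300.0)
        b = mt.simulate(p, 300.0)
        assert np.array_equal(a.L_B_series, b.L_B_series)
        assert a.t_switch == 100.0

    def test_invalid_scaling_rejected(self):
        p = mt.make_params()
        with pytest.raises(ValueError, match="dt"):
            mt.perturb_parameter(p, 10.0, {"dt": 100.0}, 100.0)
        with pytest.raises(ValueError, match="unknown"):
            mt.perturb_parameter(p, 10.0, {"speed": 0.5}, 100.0)

    def test_halved_growth_velocity_lowers_the_plateau(self):
        p = mt.make_params(seed=4)
        traj = mt.perturb_parameter(p, 2000.0, {"v_g": 0.5}, 6000.0)
        pre = traj.L_B_series[(traj.times >= 500) & (traj.times < 2000)]
        post = traj.L_B_series[traj.times >= 4000]
        assert post.mean() < 0.7 * pre.mean()

    def test_restoring_parameters_recovers_the_plateau(self):
        """A transient perturbation is reversible: simulate on, switch off
        by comparing plateaus of perturbed-then-restored vs never-perturbed."""
        p = mt.make_params(seed=14)
        down = mt.perturb_parameter(p, 1000.0, {"v_g": 0.5}, 3000.0)
        # continue from the perturbed end state with factors restored
        restored = mt.simulate(p, 3000.0,
                               initial_lengths=down.final_lengths,
                               initial_boundary=down.final_boundary,
                               rng=np.random.default_rng(123))
        unperturbed = mt.summarize(mt.simulate(p, 3000.0), 500)
        back = mt.summarize(restored, 1500.0)
        assert abs(back.mean_length - unperturbed.mean_length) < \
            4 * max(back.sd_length, unperturbed.sd_length)


class TestDensityProfile:
    def test_profile_properties(self):
        p = mt.make_params(seed=5)
        prof = mt.density_profile(p, duration=3000.0, n_snapshots=500)
        assert prof.occupancy[0] == pytest.approx(p.N_m)
        assert np.all(np.diff(prof.occupancy) <= 1e-9)
        _, _, r2 = prof.linear_fit()
        assert r2 > 0.9

    def test_boundary_occupancy_matches_contact_count(self):
        p = mt.make_params(seed=5)
        prof = mt.density_profile(p, duration=3000.0, n_snapshots=500)
        s = mt.summarize(mt.simulate(p, 3000.0), 500)
        # occupancy at the inner edge of the cortex zone (~w_c/L_B from the
        # boundary) counts the contacting tips
        mean_LB = s.mean_length / 2
        pos_cortex = 100 * (1 - p.w_c / mean_LB)
        k = np.argmin(np.abs(prof.positions - pos_cortex))
        assert prof.occupancy[k] == pytest.approx(s.mean_n_B, abs=0.5)

    def test_insufficient_snapshots_rejected(self):
        with pytest.raises(ValueError):
            mt.density_profile(mt.make_params(), duration=400.0,
                               n_snapshots=500, burn_in=500.0)


class TestLengthVsVg:
    def test_degenerate_designs_rejected(self):
        p = mt.make_params()
        with pytest.raises(ValueError, match="distinct"):
            mt.length_vs_vg_fit([15, 15, 15], p)
        with pytest.raises(ValueError, match="v_B"):
            mt.length_vs_vg_fit([0.3, 9, 15], p)

    def test_slope_strictly_positive_on_a_small_grid(self):
        fit = mt.length_vs_vg_fit([9, 12, 15], mt.make_params(seed=2),
                                  duration=2000.0, burn_in=400.0)
        assert fit.slope > 0
        assert np.all(np.diff(fit.mean_lengths) > 0)
        assert np.allclose(fit.mean_half_lengths * 2, fit.mean_lengths)


class TestParameterRecovery:
    def test_interior_catastrophe_rate_recovered_within_ci(self):
        w = mt.catastrophe_waiting_times(mt.make_params(seed=9), boundary=1e9,
                                         max_events=1200, max_duration=2e4)
        rate, lo, hi = estimate_catastrophe_rate(w)
        assert lo <= 0.3 <= hi
        assert rate == pytest.approx(0.3, rel=0.1)

    def test_growth_velocity_recovered_from_tip_displacements(self):
        traj = mt.simulate(mt.make_params(seed=9), 100.0,
                           record_interval=0.01, record_snapshots=True)
        assert estimate_growth_velocity(traj) == pytest.approx(15.0, rel=0.02)
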