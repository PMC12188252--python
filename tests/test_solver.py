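"""Width selection, mode selection, bifurcations, and oracle equivalence."""

import numpy as np
import pytest
from scipy.optimize import minimize

from morphoridge.energetics import MaterialParams
from morphoridge.pattern import GrowthSchedule
from morphoridge.solver import (
    NoFoundationError,
    PreBucklingError,
    level1_amplitude,
    level1_energy_of_sigma,
    onset_level1,
    select_mode,
    select_sigma1,
    solve_hierarchy,
    solve_level2,
    waterfill,
)


class TestSelectSigma1:
    def test_m2_closed_form_independent_of_delta(self):
        for delta in (0.2, 1.0, 7.0):
            assert select_sigma1(delta, 16.0, 2, 4) == pytest.approx(16.0**-0.25)

    def test_m4_delta_exponent(self):
        s1 = select_sigma1(1.0, 5.0, 4, 3)
        s2 = select_sigma1(4.0, 5.0, 4, 3)
        assert np.log(s2 / s1) / np.log(4.0) == pytest.approx(-0.2, abs=1e-12)

    @pytest.mark.parametrize("m", [2, 3, 4])
    @pytest.mark.parametrize("mu,delta,n1", [(0.7, 0.4, 2), (12.0, 2.5, 5)])
    def test_matches_grid_search(self, m, mu, delta, n1):
        s_star = select_sigma1(delta, mu, m, n1)
        grid = np.linspace(0.2 * s_star, 5.0 * s_star, 20001)
        vals = [level1_energy_of_sigma(s, delta, mu, m, n1) for s in grid]
        s_grid = grid[int(np.argmin(vals))]
        assert s_star == pytest.approx(s_grid, rel=1e-4)

    def test_no_foundation_error(self):
        with pytest.raises(NoFoundationError):
            select_sigma1(1.0, 0.0, 4, 2)


class TestSelectMode:
    def test_counts(self):
        assert select_mode(2.0, 0.25) == 4
        assert select_mode(1.0, 0.2) == 2

    def test_pre_buckling(self):
        with pytest.raises(PreBucklingError):
            select_mode(0.4, 0.25)

    def test_energy_decreases_with_mode_m4(self):
        # with sigma fixed, the reduced level-1 energy falls as the mode grows
        delta, mu, sigma = 1.3, 4.0, 0.3
        energies = [
            n * ((2 * delta * sigma / n) / sigma**3)
            + mu * n * (2 * delta * sigma / n) ** 2 * sigma
            for n in range(1, 7)
        ]
        # bending part is mode-independent; interaction strictly decreases
        inter = [mu * n * (2 * delta * sigma / n) ** 2 * sigma for n in range(1, 7)]
        assert all(b > a for a, b in zip(inter[1:], inter[:-1]))
        assert all(e1 > e2 for e1, e2 in zip(energies, energies[1:]))


class TestLevel1Amplitude:
    def test_values(self):
        assert level1_amplitude(0.0, 1.0, 2) == 0.0
        assert level1_amplitude(1.0, 1.0, 2) == pytest.approx(1.0)

    def test_square_root_in_time_for_linear_excess(self):
        t = np.linspace(0.01, 2.0, 50)
        a = level1_amplitude(0.7 * t, 0.5, 3)
        slope = np.polyfit(np.log(t), np.log(a), 1)[0]
        assert slope == pytest.approx(0.5, abs=1e-12)


def _bruteforce_two_level(delta, sig, Ns, mu, m):
    """Constrained 2-D minimisation of the reduced two-level energy."""

    def energy(a):
        u = a**2
        return float(
            np.sum(Ns * (u / sig**3)) + mu * np.sum(Ns * sig * a**m)
        )

    def constraint(a):
        return float(np.sum(Ns * a**2 / sig)) - 2 * delta

    best = None
    for a2_frac in (0.0, 0.2, 0.5):
        a1 = np.sqrt(2 * delta * sig[0] / Ns[0] * (1 - a2_frac))
        a2 = np.sqrt(2 * delta * sig[1] / Ns[1] * a2_frac)
        res = minimize(
            energy,
            np.array([a1, a2]),
            constraints=[{"type": "eq", "fun": constraint}],
            bounds=[(0.0, None), (0.0, None)],
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        # keep any iterate that actually satisfies the constraint
        if abs(constraint(res.x)) < 1e-8 and (best is None or res.fun < best.fun):
            best = res
    return np.abs(best.x), best.fun


class TestWaterfillOracle:
    """The exact water-filling minimiser against scipy SLSQP."""

    @pytest.mark.parametrize("m", [3, 4])
    @pytest.mark.parametrize("delta", [0.3, 1.5, 6.0])
    def test_two_level_amplitudes(self, m, delta):
        sig = np.array([0.5, 0.3])
        Ns = np.array([2.0, 1.0])
        mu = 8.0
        u, lam = waterfill(sig, Ns, delta, mu, m)
        a_ref, e_ref = _bruteforce_two_level(delta, sig, Ns, mu, m)
        a = np.sqrt(u)
        assert np.allclose(a, a_ref, rtol=1e-6, atol=1e-8)
        # constraint satisfied essentially exactly
        assert np.sum(Ns * u / sig) == pytest.approx(2 * delta, rel=1e-12)

    def test_m2_all_excess_to_cheapest_width(self):
        mu = 16.0
        s1 = mu**-0.25
        sig = np.array([s1, 0.7 * s1])
        Ns = np.array([2.0, 1.0])
        u, _ = waterfill(sig, Ns, 1.0, mu, 2)
        assert u[1] == 0.0
        assert u[0] == pytest.approx(2 * 1.0 * s1 / 2)

    def test_floors_respected(self):
        sig = np.array([0.5, 0.1])
        Ns = np.array([1.0, 2.0])
        floors = np.array([0.0, 0.04])
        u, _ = waterfill(sig, Ns, 2.0, 4.0, 4, floors=floors)
        assert np.all(u >= floors - 1e-15)
        assert np.sum(Ns * u / sig) == pytest.approx(4.0, rel=1e-12)


class TestLevel2:
    def test_m2_never_bifurcates_over_parameter_grid(self):
        """Quadratic interaction: level 2 onset condition never satisfied."""
        for mu in np.geomspace(0.1, 100.0, 5):
            for g in np.geomspace(0.01, 10.0, 5):
                params = MaterialParams(m=2, mu=float(mu))
                sch = GrowthSchedule.linear(L0=1.0, g=float(g))
                lvl1 = onset_level1(params, sch, t_max=60.0)
                assert solve_level2(params, sch, lvl1, t_max=60.0) is None

    def test_m4_bifurcates_with_zero_initial_amplitude(
        self, params4, linear_schedule, two_level_trajectory
    ):
        lvl2 = two_level_trajectory.levels[1]
        a2 = two_level_trajectory.amplitudes[2]
        t = two_level_trajectory.t
        i_on = int(np.searchsorted(t, lvl2.t_on))
        assert np.all(a2[: i_on - 1] == 0.0)
        just_after = a2[(t > lvl2.t_on) & (t <= lvl2.t_on + 0.1)]
        assert np.all(np.diff(just_after) > 0)
        assert just_after[0] < 0.2  # grows continuously from zero

    def test_solve_level2_matches_trajectory(self, params4, linear_schedule):
        lvl1 = onset_level1(params4, linear_schedule, t_max=8.0)
        lvl2 = solve_level2(params4, linear_schedule, lvl1, t_max=8.0)
        traj = solve_hierarchy(params4, linear_schedule, 8.0, max_level=2, dt=0.01)
        assert lvl2.t_on == pytest.approx(traj.levels[1].t_on, abs=1e-6)
        assert lvl2.sigma == pytest.approx(traj.levels[1].sigma, rel=1e-6)

    def test_t2_brackets_bruteforce_onset(self, params4, linear_schedule):
        """The brute-force minimiser first turns level 2 on at the algebraic t2."""
        lvl1 = onset_level1(params4, linear_schedule, t_max=8.0)
        lvl2 = solve_level2(params4, linear_schedule, lvl1, t_max=8.0)
        sig = np.array([lvl1.sigma, lvl2.sigma])
        Ns = np.array([float(lvl1.N), float(lvl2.N)])
        dt = 0.02
        grid = np.arange(lvl1.t_on + dt, 8.0, dt)
        a2 = np.array(
            [
                _bruteforce_two_level(
                    linear_schedule.delta(t), sig, Ns, params4.mu, params4.m
                )[0][1]
                for t in grid
            ]
        )
        on = grid[a2 > 1e-4]
        assert on.size > 0
        assert abs(on[0] - lvl2.t_on) <= 2 * dt


class TestHierarchy:
    def test_level_counts_follow_intercalation(self, study_trajectory):
        counts = {lv.level: lv.N for lv in study_trajectory.levels}
        assert counts[1] == 2
        assert counts[2] == 1
        assert counts[3] == 2
        assert counts[4] == 4

    def test_length_conservation_everywhere(self, study_trajectory, linear_schedule):
        t = study_trajectory.t
        total = np.zeros_like(t)
        for lv in study_trajectory.levels:
            a = study_trajectory.amplitudes[lv.level]
            total += lv.N * a**2 / lv.sigma
        active = t >= study_trajectory.levels[0].t_on
        target = 2 * linear_schedule.delta(t[active])
        assert np.max(np.abs(total[active] / target - 1)) < 1e-9

    def test_widths_shrink_with_level(self, study_trajectory):
        sigs = [lv.sigma for lv in study_trajectory.levels]
        assert all(a > b for a, b in zip(sigs, sigs[1:]))

    def test_amplitudes_nondecreasing_without_memory(self, study_trajectory):
        for lv in study_trajectory.levels:
            a = study_trajectory.amplitudes[lv.level]
            assert np.all(np.diff(a) >= -1e-12)

    def test_level1_growth_slows_after_level2(self, params4, linear_schedule):
        """da1/dt drops at t2+ relative to the run where level 2 is suppressed."""
        with_l2 = solve_hierarchy(params4, linear_schedule, 4.0, max_level=2, dt=0.01)
        without = solve_hierarchy(params4, linear_schedule, 4.0, max_level=1, dt=0.01)
        t2 = with_l2.levels[1].t_on
        t = with_l2.t
        sel = (t > t2 + 0.05) & (t < 4.0)
        rate_with = np.gradient(with_l2.amplitudes[1], t[1] - t[0])[sel]
        rate_without = np.gradient(without.amplitudes[1], t[1] - t[0])[sel]
        assert np.all(rate_with < rate_without)
        # and the counterfactual amplitude is larger
        assert np.all(without.amplitudes[1][sel] > with_l2.amplitudes[1][sel])

    def test_truncated_horizon_reports_fewer_levels(self, params4, linear_schedule):
        short = solve_hierarchy(params4, linear_schedule, 2.5, max_level=8, dt=0.01)
        assert short.n_levels < 6
        assert all(lv.t_on <= 2.5 for lv in short.levels)
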