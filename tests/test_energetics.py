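"""Closed-form Gaussian energies against independent quadrature."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from morphoridge.energetics import (
    C_BEND,
    C_LEN,
    MaterialParams,
    bump_bending,
    bump_excess_length,
    bump_interaction,
    c_interaction,
    mu_from_stiffness,
    pattern_energy,
    pattern_length,
    quadrature_pattern_energy,
    quadrature_pattern_length,
    raw_amplitude,
    reduced_amplitude,
    stiffness_from_mu,
)
from morphoridge.pattern import GaussianBump, HierarchicalPattern, place_bumps


def _gauss(a, s):
    return lambda x: a * math.exp(-(x * x) / (s * s))


def _gauss_d1(a, s):
    return lambda x: a * (-2 * x / s**2) * math.exp(-(x * x) / (s * s))


def _gauss_d2(a, s):
    return lambda x: a * (4 * x**2 / s**4 - 2 / s**2) * math.exp(-(x * x) / (s * s))


class TestReducedCoefficients:
    """Every closed-form coefficient must match adaptive quadrature to 1e-8."""

    @pytest.mark.parametrize("a,s", [(1.0, 1.0), (0.7, 0.31), (2.4, 1.7)])
    def test_bending_coefficient(self, a, s):
        d2 = _gauss_d2(a, s)
        ref, _ = quad(lambda x: 0.5 * d2(x) ** 2, -np.inf, np.inf)
        assert bump_bending(a, s) == pytest.approx(ref, rel=1e-8)

    def test_bending_value_unit_bump(self):
        # (1/2) int (y'')^2 dS for y = exp(-S^2) is (3/2) sqrt(pi/2)
        assert bump_bending(1.0, 1.0) == pytest.approx(1.5 * math.sqrt(math.pi / 2), rel=1e-12)
        assert bump_bending(1.0, 1.0) == pytest.approx(1.8800, abs=5e-5)

    @pytest.mark.parametrize("a,s", [(1.0, 1.0), (0.7, 0.31), (2.4, 1.7)])
    def test_length_coefficient(self, a, s):
        d1 = _gauss_d1(a, s)
        ref, _ = quad(lambda x: 0.5 * d1(x) ** 2, -np.inf, np.inf)
        assert bump_excess_length(a, s) == pytest.approx(ref, rel=1e-8)

    def test_length_value_unit_bump(self):
        assert bump_excess_length(1.0, 1.0) == pytest.approx(math.sqrt(math.pi / 8), rel=1e-12)
        assert bump_excess_length(1.0, 1.0) == pytest.approx(0.6267, abs=5e-5)

    @pytest.mark.parametrize("m", [2, 3, 4])
    @pytest.mark.parametrize("a,ahat,s", [(1.0, 0.0, 1.0), (1.3, 0.5, 0.4)])
    def test_interaction_coefficient(self, m, a, ahat, s):
        f = _gauss(a - ahat, s)
        ref, _ = quad(lambda x: f(x) ** m, -np.inf, np.inf)
        assert bump_interaction(a, ahat, s, m) == pytest.approx(ref, rel=1e-8)

    def test_interaction_value_unit_bump_m4(self):
        # int exp(-4 S^2) dS = sqrt(pi/4)
        assert bump_interaction(1.0, 0.0, 1.0, 4) == pytest.approx(
            math.sqrt(math.pi / 4), rel=1e-12
        )

    def test_zero_amplitude_and_relaxed(self):
        assert bump_bending(0.0, 2.0) == 0.0
        assert bump_excess_length(0.0, 1.3) == 0.0
        assert bump_interaction(0.8, 0.8, 1.0, 4) == 0.0

    def test_guards(self):
        with pytest.raises(ValueError):
            bump_bending(1.0, -1.0)
        with pytest.raises(ValueError):
            bump_excess_length(1.0, 0.0)
        with pytest.raises(ValueError, match="negative penetration"):
            bump_interaction(0.5, 0.8, 1.0, 4)


class TestScalingLaws:
    """Log-log slopes of the per-bump energies (arc ~ a^2/s, bend ~ a^2/s^3,
    substrate ~ s a^4 for the quartic interaction)."""

    def _slope(self, f, xs):
        ys = np.array([f(x) for x in xs])
        return np.polyfit(np.log(xs), np.log(ys), 1)[0]

    def test_slopes(self):
        a_grid = np.geomspace(0.1, 3.0, 12)
        s_grid = np.geomspace(0.05, 2.0, 12)
        checks = [
            (lambda a: bump_excess_length(a, 0.7), a_grid, 2.0),
            (lambda s: bump_excess_length(1.1, s), s_grid, -1.0),
            (lambda a: bump_bending(a, 0.7), a_grid, 2.0),
            (lambda s: bump_bending(1.1, s), s_grid, -3.0),
            (lambda a: bump_interaction(a, 0.0, 0.7, 4), a_grid, 4.0),
            (lambda s: bump_interaction(1.1, 0.0, s, 4), s_grid, 1.0),
        ]
        for f, xs, expected in checks:
            assert self._slope(f, xs) == pytest.approx(expected, abs=1e-6)

    def test_quadratic_amplitude_scaling(self):
        assert bump_bending(2.0, 0.9) == pytest.approx(4 * bump_bending(1.0, 0.9))


def _spread_pattern(L=6.0):
    """Two-level pattern with generous inter-bump spacing (fill ~ 0.4)."""
    sigmas = [0.35, 0.2, 0.35]
    widths = [4 * s for s in sigmas]
    centres = place_bumps(widths, L)
    amps = [0.9, 0.4, 0.9]
    lvls = [1, 2, 1]
    bumps = [
        GaussianBump(amplitude=a, sigma=s, centre=float(c), level=k)
        for a, s, c, k in zip(amps, sigmas, centres, lvls)
    ]
    return HierarchicalPattern(bumps, L)


class TestPatternEnergy:
    def test_empty_pattern_zero(self):
        params = MaterialParams(m=4, mu=1.0)
        assert pattern_energy(HierarchicalPattern([], 1.0), params).total == 0.0

    def test_single_level_reduced_form(self):
        # N1 bumps -> N1 (a^2/s^3 + mu a^m s)
        params = MaterialParams(m=4, mu=2.5)
        a, s = 0.8, 0.3
        bumps = [
            GaussianBump(amplitude=a, sigma=s, centre=c)
            for c in place_bumps([4 * s] * 3, 4.0)
        ]
        e = pattern_energy(HierarchicalPattern(bumps, 4.0), params)
        assert e.total == pytest.approx(3 * (a**2 / s**3 + 2.5 * a**4 * s), rel=1e-12)

    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_matches_quadrature_for_separated(self, m):
        params = MaterialParams(m=m, mu=1.7)
        pat = _spread_pattern()
        closed = pattern_energy(pat, params, reduced=True).total
        ref = quadrature_pattern_energy(pat, params, reduced=True)
        assert closed == pytest.approx(ref, rel=1e-6)

    def test_length_matches_quadrature(self):
        pat = _spread_pattern()
        assert pattern_length(pat) == pytest.approx(
            quadrature_pattern_length(pat), rel=1e-6
        )

    def test_level1_length_identity(self):
        # level-1 only: sum excess = N1 a1^2 / sigma1 in reduced units
        s, a = 0.4, 0.9
        bumps = [
            GaussianBump(amplitude=a, sigma=s, centre=c)
            for c in place_bumps([4 * s] * 2, 3.0)
        ]
        assert pattern_length(HierarchicalPattern(bumps, 3.0)) == pytest.approx(
            2 * a**2 / s
        )

    def test_overlap_falls_back_with_warning(self):
        params = MaterialParams(m=4, mu=1.0)
        bumps = [
            GaussianBump(amplitude=1.0, sigma=0.5, centre=-0.3),
            GaussianBump(amplitude=1.0, sigma=0.5, centre=0.3),
        ]
        pat = HierarchicalPattern(bumps, 2.0)
        with pytest.warns(UserWarning, match="overlap"):
            e = pattern_energy(pat, params)
        assert e.total == pytest.approx(
            quadrature_pattern_energy(pat, params), rel=1e-9
        )

    def test_energy_increasing_in_amplitude(self):
        params = MaterialParams(m=4, mu=1.0)
        base = _spread_pattern()
        e0 = pattern_energy(base, params).total
        for j in range(len(base.bumps)):
            bumps = [
                GaussianBump(
                    amplitude=b.amplitude * (1.25 if i == j else 1.0),
                    sigma=b.sigma,
                    centre=b.centre,
                    level=b.level,
                )
                for i, b in enumerate(base.bumps)
            ]
            assert pattern_energy(HierarchicalPattern(bumps, base.L), params).total > e0


class TestRawReducedBridge:
    def test_mu_round_trip(self):
        for m in (2, 3, 4):
            K = stiffness_from_mu(3.3, m)
            assert mu_from_stiffness(1.0, K, m) == pytest.approx(3.3, rel=1e-12)

    def test_amplitude_maps_inverse(self):
        a = np.array([0.3, 1.2])
        assert np.allclose(raw_amplitude(reduced_amplitude(a)), a)

    def test_raw_equals_scaled_reduced(self):
        # the raw energy of a pattern equals (Eb C_BEND / C_LEN) x reduced
        params = MaterialParams(m=4, mu=1.7)
        pat = _spread_pattern()
        e_red = pattern_energy(pat, params, reduced=True).total
        raw_bumps = [
            GaussianBump(
                amplitude=float(raw_amplitude(b.amplitude)),
                sigma=b.sigma,
                centre=b.centre,
                level=b.level,
            )
            for b in pat.bumps
        ]
        e_raw = pattern_energy(
            HierarchicalPattern(raw_bumps, pat.L), params, reduced=False
        ).total
        assert e_raw == pytest.approx(C_BEND / C_LEN * e_red, rel=1e-12)
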