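"""Quasi-static energy minimisation of the hierarchical bump pattern.

Reduced problem at any time ``t``: minimise

    E = sum_k N_k ( u_k / sigma_k^3 + mu sigma_k u_k^{m/2} ),   u_k = a_k^2,

subject to the excess-length constraint ``sum_k N_k u_k / sigma_k = 2 delta(t)``
and ``u_k >= 0`` (optionally ``u_k >= floor_k`` for already-recorded ridges).
The KKT conditions give a water-filling structure: active levels share the
constraint multiplier

    lambda = 1/sigma_k^2 + (m/2) mu sigma_k^2 u_k^{m/2 - 1},

which is monotone in ``u_k``, so the constrained minimiser is found exactly
(piecewise-linear in ``lambda`` for m=4, piecewise-quadratic for m=3) or by a
bracketed root for other exponents.

A new hierarchical level becomes admissible when two conditions meet:

* fit — its ``N_next = (sum_k N_k) - 1`` bumps of width ``sigma_next`` exactly
  fill the slack ``2 L(t) - sum_k 4 N_k sigma_k`` left by the frozen levels;
* marginal stability — the multiplier reaches the zero-amplitude marginal
  cost ``q(sigma_next)``, with ``q = 1/sigma^2`` for m > 2 and
  ``q = 1/sigma^2 + mu sigma^2`` for m = 2.

For m = 2 level-1 selects the width ``sigma_1 = mu^{-1/4}`` that globally
minimises ``q``, so the marginal-stability condition can never be met and no
higher level ever appears: a linear foundation force produces no hierarchy.

Widths are frozen at the instant their level appears; bifurcation times are
refined by bisection between grid points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .energetics import MaterialParams
from .pattern import GrowthSchedule, PatternTrajectory, level_counts

__all__ = [
    "LevelSolution",
    "NoFoundationError",
    "PreBucklingError",
    "select_sigma1",
    "select_mode",
    "level1_amplitude",
    "level1_energy_of_sigma",
    "onset_level1",
    "waterfill",
    "marginal_cost",
    "solve_level2",
    "solve_hierarchy",
]


class NoFoundationError(ValueError):
    """mu = 0: the width minimisation diverges (no foundation resistance)."""


class PreBucklingError(ValueError):
    """The domain cannot hold a single bump yet."""


@dataclass
class LevelSolution:
    """Frozen parameters of one hierarchical level."""

    level: int
    N: int
    sigma: float
    t_on: float

    def __post_init__(self) -> None:
        if self.N < 1 or self.sigma <= 0:
            raise ValueError("level must have N >= 1 and sigma > 0")


# ---------------------------------------------------------------------------
# level-1 width / mode / amplitude


def level1_energy_of_sigma(
    sigma: float, delta: float, mu: float, m: int, n1: int
) -> float:
    """Reduced level-1 energy with the amplitude eliminated via the constraint.

    ``E1(sigma) = 2 delta / sigma^2
                + mu N1^{1-m/2} (2 delta)^{m/2} sigma^{1+m/2}``.
    """
    two_delta = 2.0 * delta
    return two_delta / sigma**2 + mu * n1 ** (1.0 - m / 2.0) * two_delta ** (
        m / 2.0
    ) * sigma ** (1.0 + m / 2.0)


def select_sigma1(delta: float, mu: float, m: int, n1: int) -> float:
    """Energy-minimising level-1 width (closed form).

    Stationarity of ``E1(sigma)`` gives
    ``sigma1 = [ 2 (2 delta)^{1-m/2} N1^{m/2-1} / (mu (1+m/2)) ]^{1/(3+m/2)}``;
    for m=2 this is ``mu^{-1/4}`` independent of delta, for m=4 it scales as
    ``delta^{-1/5}``.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0 to select a width")
    if mu <= 0:
        raise NoFoundationError(
            "mu = 0: E1 decreases monotonically with sigma, no finite optimum"
        )
    if n1 < 1:
        raise ValueError("n1 must be >= 1")
    num = 2.0 * (2.0 * delta) ** (1.0 - m / 2.0) * n1 ** (m / 2.0 - 1.0)
    return (num / (mu * (1.0 + m / 2.0))) ** (1.0 / (3.0 + m / 2.0))


def select_mode(L: float, sigma1: float) -> int:
    """Largest bump count whose ``4 sigma1`` footprints fit in ``[-L, L]``.

    With ``sigma1`` fixed the reduced level-1 energy is non-increasing in the
    mode (strictly decreasing for m > 2), so the maximal fitting count is the
    energy-minimising one.
    """
    if L <= 0 or sigma1 <= 0:
        raise ValueError("L and sigma1 must be positive")
    n = int(math.floor(2.0 * L / (4.0 * sigma1) + 1e-12))
    if n < 1:
        raise PreBucklingError(
            f"domain 2L = {2 * L:.6g} cannot hold one bump of footprint "
            f"{4 * sigma1:.6g}"
        )
    return n


def level1_amplitude(delta, sigma1: float, n1: int):
    """Pre-bifurcation level-1 amplitude ``a1 = sqrt(2 delta sigma1 / N1)``."""
    delta = np.asarray(delta, dtype=float)
    out = np.sqrt(np.clip(2.0 * delta * sigma1 / n1, 0.0, None))
    return out if out.ndim else float(out)


def _fit_count(params: MaterialParams, L: float, delta: float, n_cap: int = 4096) -> int:
    """Largest self-consistent N with ``4 N sigma1(N, delta) <= 2 L``.

    For m > 2 the total footprint grows with N, so the search is monotone.
    Returns 0 if not even one bump fits.
    """
    if delta <= 0:
        return 0
    best = 0
    for n in range(1, n_cap + 1):
        s = select_sigma1(delta, params.mu, params.m, n)
        if 4.0 * n * s <= 2.0 * L * (1.0 + 1e-12):
            best = n
        elif best:
            break
        elif n > 8:  # footprint monotone in N; no fit is coming
            break
    return best


def onset_level1(
    params: MaterialParams,
    schedule: GrowthSchedule,
    t_max: float,
    min_mode: int = 2,
) -> LevelSolution:
    """First buckling: time, mode and width of the level-1 pattern.

    The onset time is the earliest ``t`` with ``delta(t) > 0`` at which at
    least ``min_mode`` bumps of their self-consistent width fit in the domain;
    the mode is the largest fitting count at that time and the width is then
    frozen.  ``min_mode`` defaults to 2, the base state of the intercalation
    series (a single bump leaves no gaps for higher levels to intercalate
    into).
    """
    eps = 1e-9 * max(t_max, 1.0)
    if _fit_count(params, schedule.L(eps), schedule.delta(eps)) >= min_mode and (
        schedule.delta(eps) > 0
    ):
        # the domain already holds the pattern as soon as any excess exists
        t1 = 0.0
        delta_ref = schedule.delta(eps) if schedule.delta0 == 0 else schedule.delta0
        n1 = _fit_count(params, schedule.L(eps), delta_ref)
        sigma1 = select_sigma1(delta_ref, params.mu, params.m, n1)
        return LevelSolution(1, n1, sigma1, t1)

    def gap(t: float) -> float:
        d = schedule.delta(t)
        if d <= 0:
            return -1.0
        s = select_sigma1(d, params.mu, params.m, min_mode)
        return 2.0 * schedule.L(t) - 4.0 * min_mode * s

    if gap(t_max) < 0:
        raise PreBucklingError(
            f"no level-1 onset with mode >= {min_mode} before t = {t_max}"
        )
    t1 = brentq(gap, eps, t_max, xtol=1e-12, rtol=1e-14)
    n1 = max(min_mode, _fit_count(params, schedule.L(t1), schedule.delta(t1)))
    sigma1 = select_sigma1(schedule.delta(t1), params.mu, params.m, n1)
    return LevelSolution(1, n1, sigma1, t1)


# ---------------------------------------------------------------------------
# constrained amplitude minimisation (water-filling in u = a^2)


def marginal_cost(sigma, mu: float, m: int):
    """Zero-amplitude marginal energy per unit excess length, ``q(sigma)``."""
    sigma = np.asarray(sigma, dtype=float)
    if m == 2:
        out = 1.0 / sigma**2 + mu * sigma**2
    else:
        out = 1.0 / sigma**2
    return out if out.ndim else float(out)


def waterfill(
    sigmas: np.ndarray,
    Ns: np.ndarray,
    delta: float,
    mu: float,
    m: int,
    floors: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Exact constrained minimiser ``u_k`` and multiplier ``lambda``.

    ``floors`` are lower bounds on ``u_k`` (already-recorded ridge amplitudes
    that cannot shrink); the constraint is
    ``sum N_k u_k / sigma_k = 2 delta`` and must be feasible
    (``2 delta >= sum N_k floor_k / sigma_k``).
    """
    sigmas = np.asarray(sigmas, dtype=float)
    Ns = np.asarray(Ns, dtype=float)
    if floors is None:
        floors = np.zeros_like(sigmas)
    floors = np.asarray(floors, dtype=float)
    target = 2.0 * delta
    base = float(np.sum(Ns * floors / sigmas))
    if target < base - 1e-12 * max(base, 1.0):
        raise ValueError(
            f"infeasible constraint: floors already carry {base:.6g} > 2 delta = {target:.6g}"
        )
    if target <= base:
        return floors.copy(), float(np.min(marginal_cost(sigmas, mu, m)))
    b = 1.0 / sigmas**2
    if m == 2:
        # energy linear in u: all free excess goes to the cheapest width
        q = marginal_cost(sigmas, mu, m)
        u = floors.copy()
        k = int(np.argmin(q))
        u[k] += (target - base) * sigmas[k] / Ns[k]
        return u, float(q[k])

    # thresholds: level k grows beyond its floor once lambda exceeds lam_hat_k
    lam_hat = b + (m / 2.0) * mu * sigmas**2 * floors ** (m / 2.0 - 1.0)

    def u_of_lam(lam: float) -> np.ndarray:
        excess = np.clip(lam - b, 0.0, None)
        grow = (2.0 * excess / (m * mu * sigmas**2)) ** (2.0 / (m - 2.0))
        return np.maximum(floors, grow)

    def g(lam: float) -> float:
        return float(np.sum(Ns * u_of_lam(lam) / sigmas)) - target

    if m == 4:
        # piecewise linear in lambda: solve the active segment exactly.
        # Levels with lam_hat below the segment grow past their floor and
        # contribute N (lam - b)/(2 mu sigma^3); the rest sit at their floor.
        order = np.argsort(lam_hat)
        for j in range(1, len(order) + 1):
            act = order[:j]
            inact = order[j:]
            fixed = (
                float(np.sum(Ns[inact] * floors[inact] / sigmas[inact]))
                if len(inact)
                else 0.0
            )
            w = Ns[act] / (2.0 * mu * sigmas[act] ** 3)
            lam = (target - fixed + float(np.sum(w * b[act]))) / float(np.sum(w))
            lam_lo = lam_hat[order[j - 1]]
            lam_up = lam_hat[order[j]] if j < len(order) else np.inf
            tol = 1e-12 * max(abs(lam_lo), 1.0)
            if lam_lo - tol <= lam <= lam_up + tol:
                return u_of_lam(lam), float(lam)
        # fall through to bracketed root (degenerate floors/ties)

    lam_lo = float(np.min(lam_hat)) - 1.0
    lam_hi = float(np.max(lam_hat)) + 1.0
    while g(lam_hi) < 0.0:
        lam_hi = lam_lo + 2.0 * (lam_hi - lam_lo)
        if lam_hi - lam_lo > 1e18:
            raise RuntimeError("water-filling multiplier bracket failed")
    lam = brentq(g, lam_lo, lam_hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    return u_of_lam(lam), float(lam)


# ---------------------------------------------------------------------------
# hierarchy marching


def _slack_sigma(levels: list[LevelSolution], n_next: int, L: float) -> float:
    """Width of the next level if its bumps exactly fill the current slack."""
    occupied = sum(4.0 * lv.N * lv.sigma for lv in levels)
    return (2.0 * L - occupied) / (4.0 * n_next)


def _onset_indicator(
    params: MaterialParams,
    schedule: GrowthSchedule,
    levels: list[LevelSolution],
    n_next: int,
    floors_map: dict[int, float] | None = None,
):
    """phi(t) = lambda(t) - q(sigma_next(t)); onset at the upward crossing."""

    sigmas = np.array([lv.sigma for lv in levels])
    Ns = np.array([float(lv.N) for lv in levels])
    floors = (
        np.array([floors_map.get(lv.level, 0.0) for lv in levels])
        if floors_map
        else None
    )

    def phi(t: float) -> float:
        s_next = _slack_sigma(levels, n_next, schedule.L(t))
        if s_next <= 0:
            return -np.inf
        _, lam = waterfill(sigmas, Ns, schedule.delta(t), params.mu, params.m, floors)
        return lam - marginal_cost(s_next, params.mu, params.m)

    return phi


def solve_level2(
    params: MaterialParams,
    schedule: GrowthSchedule,
    level1: LevelSolution,
    t_max: float,
) -> LevelSolution | None:
    """Level-2 width and bifurcation time, or ``None`` if level 2 never onsets.

    The width ``sigma2`` and time ``t2`` simultaneously satisfy the fit
    condition ``4 N1 sigma1 + 4 N2 sigma2 = 2 L(t2)`` and marginal stability
    of the two-level energy; ``N2 = N1 - 1`` from intercalation.  For m = 2 the
    marginal condition is provably never met (returns ``None``).
    """
    n2 = level1.N - 1
    if n2 < 1:
        return None
    phi = _onset_indicator(params, schedule, [level1], n2)
    t_lo = max(level1.t_on, 1e-9)
    if phi(t_max) <= 0:
        return None
    # find a strictly-negative left bracket (phi -> -inf while slack <= 0)
    lo = t_lo
    if not np.isfinite(phi(lo)) or phi(lo) < 0:
        t2 = brentq(lambda t: phi(t) if np.isfinite(phi(t)) else -1e30, lo, t_max,
                    xtol=1e-12, rtol=1e-14)
    else:
        t2 = lo
    sigma2 = _slack_sigma([level1], n2, schedule.L(t2))
    return LevelSolution(2, n2, sigma2, t2)


def solve_hierarchy(
    params: MaterialParams,
    schedule: GrowthSchedule,
    t_max: float,
    max_level: int = 8,
    dt: float = 0.01,
    min_mode: int = 2,
    floors_map: dict[int, float] | None = None,
) -> PatternTrajectory:
    """March the quasi-static hierarchy on a uniform time grid.

    Returns a :class:`PatternTrajectory` with amplitude curves for every level
    whose onset time falls inside the horizon.  Levels are added one at a
    time; each onset time is refined by bisection between grid points and the
    new width is frozen at the refined time.
    """
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    lvl1 = onset_level1(params, schedule, t_max, min_mode=min_mode)
    levels = [lvl1]
    t = np.arange(0.0, t_max + 0.5 * dt, dt)
    amps: dict[int, np.ndarray] = {1: np.zeros_like(t)}

    def seq_counts(depth: int) -> list[int]:
        return level_counts(lvl1.N, depth)

    for i, ti in enumerate(t):
        if ti < lvl1.t_on or schedule.delta(ti) <= 0:
            continue
        # check for onset of the next level within (t[i-1], t[i]]
        while len(levels) < max_level:
            depth = len(levels)
            n_next = seq_counts(depth + 1)[depth]
            phi = _onset_indicator(params, schedule, levels, n_next, floors_map)
            if phi(ti) <= 0:
                break
            lo = max(t[i - 1] if i > 0 else 0.0, lvl1.t_on)
            if phi(lo) >= 0 and lo <= lvl1.t_on + dt:
                t_on = lo
            else:
                t_on = brentq(
                    lambda tau: phi(tau) if np.isfinite(phi(tau)) else -1e30,
                    lo,
                    ti,
                    xtol=1e-12,
                    rtol=1e-14,
                )
            s_new = _slack_sigma(levels, n_next, schedule.L(t_on))
            levels.append(LevelSolution(depth + 1, n_next, s_new, t_on))
            amps[depth + 1] = np.zeros_like(t)
        sigmas = np.array([lv.sigma for lv in levels if lv.t_on <= ti])
        Ns = np.array([float(lv.N) for lv in levels if lv.t_on <= ti])
        floors = (
            np.array(
                [floors_map.get(lv.level, 0.0) for lv in levels if lv.t_on <= ti]
            )
            if floors_map
            else None
        )
        u, _ = waterfill(sigmas, Ns, schedule.delta(ti), params.mu, params.m, floors)
        for lv, uk in zip([lv for lv in levels if lv.t_on <= ti], u):
            amps[lv.level][i] = math.sqrt(max(uk, 0.0))

    return PatternTrajectory(
        t=t,
        levels=levels,
        amplitudes=amps,
        memory_amplitudes={lv.level: np.zeros_like(t) for lv in levels},
        schedule=schedule,
    )
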