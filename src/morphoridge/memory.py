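"""Remodelling (memory) dynamics of the foundation profile.

The foundation's rest shape relaxes towards the deformed shape,
``d yhat / dt = eta (y - yhat)``.  Within the Gaussian reduction the relaxed
profile shares widths and centres with the pattern, so the law becomes one
exponential relaxation per level amplitude, ``ahat_k -> a_k``.  The
interaction energy is then built on the deviation ``a_k - ahat_k``: levels
that have been deformed for a long time are cheap to push further, which is
what preserves the amplitude ordering by hierarchical level.

Time stepping is operator splitting: a quasi-static constrained minimisation
with the current memory amplitudes, followed by the exact exponential memory
update over ``dt`` (switchable to relax-first).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .energetics import MaterialParams
from .pattern import GrowthSchedule, PatternTrajectory, level_counts
from .solver import (
    LevelSolution,
    _slack_sigma,
    marginal_cost,
    onset_level1,
    solve_hierarchy,
    waterfill,
)

__all__ = ["step_memory", "waterfill_memory", "evolve_with_memory"]


def step_memory(ahat, a, eta: float, dt: float):
    """Exact exponential relaxation ``ahat' = a + (ahat - a) exp(-eta dt)``.

    ``a`` is held fixed over the step; ``eta = 0`` leaves ``ahat`` unchanged
    and ``eta dt -> inf`` gives instantaneous relaxation to ``a``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if eta < 0:
        raise ValueError("eta must be >= 0")
    ahat = np.asarray(ahat, dtype=float)
    a = np.asarray(a, dtype=float)
    if eta == 0.0:
        out = ahat + 0.0 * a  # no remodelling: ahat unchanged (broadcast)
    else:
        out = a + (ahat - a) * math.exp(-eta * dt)
    return out if out.ndim else float(out)


def _amplitudes_given_lambda(
    lam: float,
    sigmas: np.ndarray,
    ahats: np.ndarray,
    mu: float,
    m: int,
    iters: int = 100,
) -> np.ndarray:
    """Per-level stationarity ``lam = 1/s^2 + (m/2) mu s^2 (a-ahat)^{m-1}/a``.

    The right-hand side is monotone non-decreasing in ``a`` (on ``a > 0`` for
    even m, on ``a >= ahat`` for odd m), so a vectorised bisection suffices.
    """
    b = 1.0 / sigmas**2
    cm = 0.5 * m * mu * sigmas**2

    def lam_of_a(a: np.ndarray) -> np.ndarray:
        dev = a - ahats
        if m % 2 == 1:
            dev = np.clip(dev, 0.0, None)
        return b + cm * dev ** (m - 1) / np.maximum(a, 1e-300)

    lo = np.full_like(sigmas, 1e-12)
    if m % 2 == 1:
        lo = np.maximum(lo, ahats)
    hi = np.maximum(ahats, 1.0) + 1.0
    for _ in range(200):
        bad = lam_of_a(hi) < lam
        if not bad.any():
            break
        hi[bad] *= 2.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        high = lam_of_a(mid) > lam
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    a = 0.5 * (lo + hi)
    # levels that cannot reach lam even at a -> 0 stay flat
    if m % 2 == 0:
        a = np.where((ahats == 0.0) & (b >= lam), 0.0, a)
    else:
        a = np.where((b >= lam) & (ahats == 0.0), 0.0, a)
    return a


def waterfill_memory(
    sigmas: np.ndarray,
    Ns: np.ndarray,
    ahats: np.ndarray,
    delta: float,
    mu: float,
    m: int,
) -> tuple[np.ndarray, float]:
    """Constrained minimiser with memory-shifted interaction terms.

    Minimises ``sum N (a^2/s^3 + mu s (a - ahat)^m)`` subject to
    ``sum N a^2 / s = 2 delta``.  When all memory amplitudes vanish this
    delegates to the memoryless :func:`morphoridge.solver.waterfill`, so the
    eta = 0 path is bit-identical to the memoryless solver.
    """
    sigmas = np.asarray(sigmas, dtype=float)
    Ns = np.asarray(Ns, dtype=float)
    ahats = np.asarray(ahats, dtype=float)
    if not ahats.any():
        u, lam = waterfill(sigmas, Ns, delta, mu, m)
        return np.sqrt(u), lam
    target = 2.0 * delta

    def g(lam: float) -> float:
        a = _amplitudes_given_lambda(lam, sigmas, ahats, mu, m)
        return float(np.sum(Ns * a * a / sigmas)) - target

    b = 1.0 / sigmas**2
    lam_lo = float(np.min(b)) - 1.0
    while g(lam_lo) > 0.0:
        lam_lo -= 2.0 * abs(lam_lo) + 1.0
        if lam_lo < -1e12:
            raise RuntimeError("memory water-filling lower bracket failed")
    lam_hi = float(np.max(b)) + 1.0
    while g(lam_hi) < 0.0:
        lam_hi *= 2.0
        if lam_hi > 1e15:
            raise RuntimeError("memory water-filling upper bracket failed")
    lam = brentq(g, lam_lo, lam_hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    return _amplitudes_given_lambda(lam, sigmas, ahats, mu, m), float(lam)


def evolve_with_memory(
    params: MaterialParams,
    schedule: GrowthSchedule,
    t_max: float,
    max_level: int = 8,
    dt: float = 0.01,
    min_mode: int = 2,
    order: str = "minimize_first",
) -> PatternTrajectory:
    """Hierarchy evolution with foundation remodelling at rate ``params.eta``.

    Alternates quasi-static minimisation (with interaction terms built on
    ``a_k - ahat_k``) and the exact memory relaxation.  ``eta = 0`` reproduces
    :func:`morphoridge.solver.solve_hierarchy` exactly on the same grid.
    A newly bifurcated level starts with zero memory amplitude.
    """
    if order not in ("minimize_first", "relax_first"):
        raise ValueError("order must be 'minimize_first' or 'relax_first'")
    if params.eta == 0.0:
        return solve_hierarchy(
            params, schedule, t_max, max_level=max_level, dt=dt, min_mode=min_mode
        )
    lvl1 = onset_level1(params, schedule, t_max, min_mode=min_mode)
    levels = [lvl1]
    t = np.arange(0.0, t_max + 0.5 * dt, dt)
    amps: dict[int, np.ndarray] = {1: np.zeros_like(t)}
    hats: dict[int, np.ndarray] = {1: np.zeros_like(t)}
    ahat_now: dict[int, float] = {1: 0.0}
    a_now: dict[int, float] = {1: 0.0}

    def active(ti: float) -> list[LevelSolution]:
        return [lv for lv in levels if lv.t_on <= ti]

    def lam_at(ti: float) -> float:
        act = active(ti)
        sig = np.array([lv.sigma for lv in act])
        N = np.array([float(lv.N) for lv in act])
        ah = np.array([ahat_now[lv.level] for lv in act])
        _, lam = waterfill_memory(sig, N, ah, schedule.delta(ti), params.mu, params.m)
        return lam

    prev_t = 0.0
    for i, ti in enumerate(t):
        if ti < lvl1.t_on or schedule.delta(ti) <= 0:
            prev_t = ti
            continue
        # onset check for the next level (memory amplitudes held at current
        # values while bisecting inside the step)
        while len(levels) < max_level:
            depth = len(levels)
            n_next = level_counts(lvl1.N, depth + 1)[depth]

            def phi(tau: float) -> float:
                s_next = _slack_sigma(levels, n_next, schedule.L(tau))
                if s_next <= 0:
                    return -1e30
                return lam_at(tau) - marginal_cost(s_next, params.mu, params.m)

            if phi(ti) <= 0:
                break
            lo = max(prev_t, lvl1.t_on)
            t_on = lo if phi(lo) >= 0 else brentq(
                phi, lo, ti, xtol=1e-12, rtol=1e-14
            )
            s_new = _slack_sigma(levels, n_next, schedule.L(t_on))
            levels.append(LevelSolution(depth + 1, n_next, s_new, t_on))
            amps[depth + 1] = np.zeros_like(t)
            hats[depth + 1] = np.zeros_like(t)
            ahat_now[depth + 1] = 0.0
            a_now[depth + 1] = 0.0

        act = active(ti)
        sig = np.array([lv.sigma for lv in act])
        N = np.array([float(lv.N) for lv in act])
        step = ti - prev_t if ti > prev_t else dt

        if order == "relax_first":
            for lv in act:
                ahat_now[lv.level] = step_memory(
                    ahat_now[lv.level], a_now[lv.level], params.eta, step
                )
        ah = np.array([ahat_now[lv.level] for lv in act])
        a, _ = waterfill_memory(sig, N, ah, schedule.delta(ti), params.mu, params.m)
        for lv, ak in zip(act, a):
            a_now[lv.level] = float(ak)
        if order == "minimize_first":
            for lv in act:
                ahat_now[lv.level] = step_memory(
                    ahat_now[lv.level], a_now[lv.level], params.eta, step
                )
        for lv in act:
            amps[lv.level][i] = a_now[lv.level]
            hats[lv.level][i] = ahat_now[lv.level]
        prev_t = ti

    return PatternTrajectory(
        t=t, levels=levels, amplitudes=amps, memory_amplitudes=hats, schedule=schedule
    )
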