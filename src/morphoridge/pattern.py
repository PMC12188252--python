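"""Domain types for hierarchical Gaussian-bump patterns on a growing domain.

The deformed interface between two growing elastic layers is modelled as a
sum of isolated Gaussian bumps ``y(S) = sum_i a_i exp(-(S - S_i)^2 / sigma_i^2)``
on the symmetric domain ``S in [-L, L]``.  Each bump belongs to a hierarchical
level: level 1 bumps appear first and are largest, higher levels are
intercalated into the gaps as the domain grows.  A bump's footprint — the
portion of the domain it is considered to occupy — is ``4 sigma`` wide.

All lengths here are in reduced units (domain lengths in units of the initial
half-length, amplitudes in the reduced convention of
:mod:`morphoridge.energetics`); time is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GaussianBump",
    "HierarchicalPattern",
    "GrowthSchedule",
    "PatternTrajectory",
    "intercalation_sequence",
    "level_counts",
    "place_bumps",
    "advect_bumps",
]

FOOTPRINT_FACTOR = 4.0  # a bump of width parameter sigma occupies 4*sigma


@dataclass
class GaussianBump:
    """One Gaussian bump: ``y(S) = amplitude * exp(-(S-centre)^2/sigma^2)``.

    ``memory_amplitude`` is the amplitude of the relaxed (remodelled)
    foundation profile co-centred with the bump; it starts at zero and is
    relaxed towards ``amplitude``, so it never exceeds it under the
    exponential relaxation law.
    """

    amplitude: float
    sigma: float
    centre: float = 0.0
    level: int = 1
    memory_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if int(self.level) != self.level or self.level < 1:
            raise ValueError(f"level must be an integer >= 1, got {self.level}")
        self.level = int(self.level)
        if self.memory_amplitude < 0:
            raise ValueError("memory amplitude must be >= 0")

    @property
    def footprint(self) -> float:
        """Width of the domain interval the bump occupies (``4 sigma``)."""
        return FOOTPRINT_FACTOR * self.sigma

    def profile(self, S: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-((S - self.centre) ** 2) / self.sigma**2)

    def profile_d1(self, S: np.ndarray) -> np.ndarray:
        u = S - self.centre
        return self.amplitude * (-2.0 * u / self.sigma**2) * np.exp(-(u**2) / self.sigma**2)

    def profile_d2(self, S: np.ndarray) -> np.ndarray:
        u = S - self.centre
        s2 = self.sigma**2
        return self.amplitude * (4.0 * u**2 / s2**2 - 2.0 / s2) * np.exp(-(u**2) / s2)

    def memory_profile(self, S: np.ndarray) -> np.ndarray:
        return self.memory_amplitude * np.exp(
            -((S - self.centre) ** 2) / self.sigma**2
        )


def intercalation_sequence(n1: int, depth: int) -> list[int]:
    """Left-to-right level labels after ``depth`` rounds of intercalation.

    Starting from ``n1`` level-1 bumps, each new level inserts one bump into
    every gap between adjacent existing bumps, so the count at level ``k+1``
    equals (number of labels at depth ``k``) - 1.  For ``n1 = 2`` the series
    runs 1.1 -> 1.2.1 -> 1.3.2.3.1 -> 1.4.3.4.2.4.3.4.1 -> ...
    """
    if int(n1) != n1 or n1 < 2:
        raise ValueError(f"n1 must be an integer >= 2, got {n1}")
    if int(depth) != depth or depth < 1:
        raise ValueError(f"depth must be an integer >= 1, got {depth}")
    seq = [1] * int(n1)
    for level in range(2, int(depth) + 1):
        out: list[int] = []
        for i, label in enumerate(seq):
            out.append(label)
            if i + 1 < len(seq):
                out.append(level)
        seq = out
    return seq


def level_counts(n1: int, depth: int) -> list[int]:
    """Number of bumps at each level, ``[N_1, ..., N_depth]``."""
    seq = intercalation_sequence(n1, depth)
    return [seq.count(k) for k in range(1, int(depth) + 1)]


def place_bumps(widths: Sequence[float], L: float) -> np.ndarray:
    """Equal-gap centres for footprints of the given widths inside ``[-L, L]``.

    The free space ``2L - sum(widths)`` is split into equal gaps before,
    between and after the footprints.  Raises ``ValueError`` if the footprints
    do not fit.  A single bump is centred at the origin by symmetry.
    """
    widths = np.asarray(widths, dtype=float)
    if widths.ndim != 1 or widths.size == 0:
        raise ValueError("widths must be a non-empty 1-D sequence")
    total = float(widths.sum())
    free = 2.0 * L - total
    if free < -1e-12 * max(2.0 * L, 1.0):
        raise ValueError(
            f"insufficient domain: footprints sum to {total:.6g} > 2L = {2 * L:.6g}"
        )
    gap = max(free, 0.0) / (widths.size + 1)
    edges = -L + gap + np.concatenate(([0.0], np.cumsum(widths[:-1] + gap)))
    return edges + widths / 2.0


def advect_bumps(centres: Sequence[float], L_old: float, L_new: float) -> np.ndarray:
    """Affine advection of bump centres as the domain grows uniformly."""
    if L_old <= 0 or L_new <= 0:
        raise ValueError("domain half-lengths must be positive")
    return np.asarray(centres, dtype=float) * (L_new / L_old)


@dataclass
class HierarchicalPattern:
    """Ordered set of Gaussian bumps on ``[-L, L]`` with level bookkeeping.

    All bumps of one level share the same width and amplitude.  Adjacent
    footprints must not overlap (touching is allowed).
    """

    bumps: list[GaussianBump]
    L: float

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("domain half-length must be positive")
        self.bumps = sorted(self.bumps, key=lambda b: b.centre)

    # -- level bookkeeping -------------------------------------------------
    @property
    def levels(self) -> list[int]:
        return sorted({b.level for b in self.bumps})

    @property
    def counts(self) -> dict[int, int]:
        return {k: sum(1 for b in self.bumps if b.level == k) for k in self.levels}

    @property
    def sigmas(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for b in self.bumps:
            prev = out.setdefault(b.level, b.sigma)
            if abs(prev - b.sigma) > 1e-12 * max(prev, 1.0):
                raise ValueError(f"bumps of level {b.level} do not share a width")
        return out

    @property
    def amplitudes(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for b in self.bumps:
            prev = out.setdefault(b.level, b.amplitude)
            if abs(prev - b.amplitude) > 1e-12 * max(prev, 1.0):
                raise ValueError(
                    f"bumps of level {b.level} do not share an amplitude"
                )
        return out

    @property
    def sequence(self) -> list[int]:
        """Left-to-right level labels."""
        return [b.level for b in self.bumps]

    def total_footprint(self) -> float:
        return sum(b.footprint for b in self.bumps)

    def fits(self) -> bool:
        return self.total_footprint() <= 2.0 * self.L * (1.0 + 1e-12)

    def separated(self, tol: float = 1e-9) -> bool:
        """True if adjacent footprints are disjoint (touching allowed)."""
        for left, right in zip(self.bumps, self.bumps[1:]):
            if right.centre - left.centre < 2.0 * (left.sigma + right.sigma) - tol:
                return False
        return True

    def profile(self, S: np.ndarray) -> np.ndarray:
        y = np.zeros_like(np.asarray(S, dtype=float))
        for b in self.bumps:
            y += b.profile(S)
        return y

    def profile_d1(self, S: np.ndarray) -> np.ndarray:
        y = np.zeros_like(np.asarray(S, dtype=float))
        for b in self.bumps:
            y += b.profile_d1(S)
        return y

    def profile_d2(self, S: np.ndarray) -> np.ndarray:
        y = np.zeros_like(np.asarray(S, dtype=float))
        for b in self.bumps:
            y += b.profile_d2(S)
        return y

    def memory_profile(self, S: np.ndarray) -> np.ndarray:
        y = np.zeros_like(np.asarray(S, dtype=float))
        for b in self.bumps:
            y += b.memory_profile(S)
        return y

    # -- geometry updates --------------------------------------------------
    def placed(self, L: float | None = None) -> "HierarchicalPattern":
        """Fresh equal-gap layout at half-length ``L`` (default: current)."""
        L = self.L if L is None else L
        widths = [b.footprint for b in self.bumps]
        centres = place_bumps(widths, L)
        bumps = [replace(b, centre=c) for b, c in zip(self.bumps, centres)]
        return HierarchicalPattern(bumps, L)

    def advected(self, L_new: float) -> "HierarchicalPattern":
        """Affinely advect all centres as the domain grows to ``L_new``."""
        bumps = [
            replace(b, centre=c)
            for b, c in zip(self.bumps, advect_bumps([b.centre for b in self.bumps], self.L, L_new))
        ]
        return HierarchicalPattern(bumps, L_new)

    # -- serialization -----------------------------------------------------
    def to_records(self) -> list[dict]:
        return [
            {
                "level": b.level,
                "amplitude": b.amplitude,
                "sigma": b.sigma,
                "centre": b.centre,
                "memory_amplitude": b.memory_amplitude,
            }
            for b in self.bumps
        ]

    @classmethod
    def from_records(cls, records: Sequence[dict], L: float) -> "HierarchicalPattern":
        return cls(
            [
                GaussianBump(
                    amplitude=r["amplitude"],
                    sigma=r["sigma"],
                    centre=r["centre"],
                    level=r["level"],
                    memory_amplitude=r.get("memory_amplitude", 0.0),
                )
                for r in records
            ],
            L,
        )


@dataclass
class GrowthSchedule:
    """Time courses of the domain half-length L(t) and excess half-length δ(t).

    The default ("linear") schedule is ``L(t) = L0 (1 + growth_rate * t)`` and
    ``delta(t) = delta0 + g * L0 * t``: the excess length between the layers
    increases at a constant rate characterised by the dimensionless parameter
    ``g``.  A "burst" schedule keeps L fixed while δ ramps rapidly, as in
    spine dilation.  ``delta0`` defaults to zero (no excess at t = 0); a
    positive value represents an observation window that starts after some
    excess has already accumulated.
    """

    L0: float
    g: float
    growth_rate: float = 1.0
    delta0: float = 0.0
    kind: str = "linear"

    def __post_init__(self) -> None:
        if self.L0 <= 0:
            raise ValueError("L0 must be positive")
        if self.g < 0 or self.growth_rate < 0 or self.delta0 < 0:
            raise ValueError("g, growth_rate and delta0 must be >= 0")
        if self.kind not in ("linear", "burst"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")

    @classmethod
    def linear(cls, L0: float, g: float, growth_rate: float = 1.0, delta0: float = 0.0):
        return cls(L0=L0, g=g, growth_rate=growth_rate, delta0=delta0, kind="linear")

    @classmethod
    def burst(cls, L0: float, g: float, delta0: float = 0.0):
        """Burst growth: the domain is frozen while the excess ramps at g*L0."""
        return cls(L0=L0, g=g, growth_rate=0.0, delta0=delta0, kind="burst")

    def L(self, t):
        t = np.asarray(t, dtype=float)
        out = self.L0 * (1.0 + self.growth_rate * t)
        return out if out.ndim else float(out)

    def delta(self, t):
        t = np.asarray(t, dtype=float)
        out = self.delta0 + self.g * self.L0 * t
        return out if out.ndim else float(out)

    def l(self, t):
        """Half-length of the longer layer, ``l(t) = L(t) + delta(t)``."""
        return self.L(t) + self.delta(t)


@dataclass
class PatternTrajectory:
    """Time series of a hierarchical pattern.

    ``levels`` holds one record per hierarchical level with attributes
    ``level``, ``N``, ``sigma`` and ``t_on`` (the bifurcation time).
    ``amplitudes[k]`` and ``memory_amplitudes[k]`` are arrays over ``t`` for
    level ``k`` (zero before onset).
    """

    t: np.ndarray
    levels: list  # records with .level, .N, .sigma, .t_on
    amplitudes: dict[int, np.ndarray]
    memory_amplitudes: dict[int, np.ndarray] = field(default_factory=dict)
    schedule: GrowthSchedule | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for k, a in self.amplitudes.items():
            if len(a) != len(self.t):
                raise ValueError(f"amplitude curve for level {k} has wrong length")

    @property
    def bifurcation_times(self) -> dict[int, float]:
        return {lv.level: lv.t_on for lv in self.levels}

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_record(self, level: int):
        for lv in self.levels:
            if lv.level == level:
                return lv
        raise KeyError(f"no level {level} in trajectory")

    def active_levels(self, i: int) -> list:
        ti = self.t[i]
        return [lv for lv in self.levels if lv.t_on <= ti]

    def pattern_at(self, i: int) -> HierarchicalPattern:
        """Snapshot at time index ``i`` with an equal-gap bump layout."""
        if self.schedule is None:
            raise ValueError("trajectory has no growth schedule attached")
        ti = self.t[i]
        active = self.active_levels(i)
        if not active:
            raise ValueError(f"no active levels at t = {ti}")
        depth = max(lv.level for lv in active)
        base = next(lv for lv in active if lv.level == 1)
        seq = intercalation_sequence(base.N, depth)
        by_level = {lv.level: lv for lv in active}
        bumps = []
        for label in seq:
            lv = by_level[label]
            bumps.append(
                GaussianBump(
                    amplitude=float(self.amplitudes[label][i]),
                    sigma=lv.sigma,
                    level=label,
                    memory_amplitude=float(
                        self.memory_amplitudes.get(label, np.zeros_like(self.t))[i]
                    ),
                )
            )
        widths = [b.footprint for b in bumps]
        centres = place_bumps(widths, float(self.schedule.L(ti)))
        for b, c in zip(bumps, centres):
            b.centre = float(c)
        return HierarchicalPattern(bumps, float(self.schedule.L(ti)))
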