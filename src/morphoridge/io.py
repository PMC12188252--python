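"""Lossless CSV / JSON writers and readers for trajectories and patterns."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pattern import GrowthSchedule, HierarchicalPattern, PatternTrajectory
from .solver import LevelSolution

__all__ = [
    "trajectory_to_frame",
    "trajectory_to_csv",
    "trajectory_from_csv",
    "trajectory_to_json",
    "trajectory_from_json",
    "pattern_to_json",
    "pattern_from_json",
    "pattern_to_csv",
]


def trajectory_to_frame(traj: PatternTrajectory) -> pd.DataFrame:
    """Long-format frame: one row per (time, level)."""
    rows = []
    for lv in traj.levels:
        a = traj.amplitudes[lv.level]
        ah = traj.memory_amplitudes.get(lv.level, np.zeros_like(traj.t))
        for i, ti in enumerate(traj.t):
            rows.append(
                {
                    "t": ti,
                    "level": lv.level,
                    "N": lv.N,
                    "sigma": lv.sigma,
                    "t_on": lv.t_on,
                    "a": a[i],
                    "a_hat": ah[i],
                }
            )
    return pd.DataFrame(rows)


def _schedule_meta(schedule: GrowthSchedule | None) -> dict:
    if schedule is None:
        return {}
    return {
        "L0": schedule.L0,
        "g": schedule.g,
        "growth_rate": schedule.growth_rate,
        "delta0": schedule.delta0,
        "kind": schedule.kind,
    }


def trajectory_to_csv(traj: PatternTrajectory, path: str | Path) -> Path:
    path = Path(path)
    trajectory_to_frame(traj).to_csv(path, index=False, float_format="%.17g")
    return path


def trajectory_from_csv(
    path: str | Path, schedule: GrowthSchedule | None = None
) -> PatternTrajectory:
    df = pd.read_csv(path)
    t = np.sort(df["t"].unique())
    levels = []
    amps: dict[int, np.ndarray] = {}
    hats: dict[int, np.ndarray] = {}
    for level, grp in df.groupby("level"):
        grp = grp.sort_values("t")
        levels.append(
            LevelSolution(
                level=int(level),
                N=int(grp["N"].iloc[0]),
                sigma=float(grp["sigma"].iloc[0]),
                t_on=float(grp["t_on"].iloc[0]),
            )
        )
        amps[int(level)] = grp["a"].to_numpy()
        hats[int(level)] = grp["a_hat"].to_numpy()
    levels.sort(key=lambda lv: lv.level)
    return PatternTrajectory(
        t=t, levels=levels, amplitudes=amps, memory_amplitudes=hats, schedule=schedule
    )


def trajectory_to_json(traj: PatternTrajectory, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "t": traj.t.tolist(),
        "levels": [
            {"level": lv.level, "N": lv.N, "sigma": lv.sigma, "t_on": lv.t_on}
            for lv in traj.levels
        ],
        "amplitudes": {str(k): v.tolist() for k, v in traj.amplitudes.items()},
        "memory_amplitudes": {
            str(k): v.tolist() for k, v in traj.memory_amplitudes.items()
        },
        "schedule": _schedule_meta(traj.schedule),
    }
    path.write_text(json.dumps(payload))
    return path


def trajectory_from_json(path: str | Path) -> PatternTrajectory:
    payload = json.loads(Path(path).read_text())
    schedule = (
        GrowthSchedule(**payload["schedule"]) if payload.get("schedule") else None
    )
    return PatternTrajectory(
        t=np.asarray(payload["t"]),
        levels=[LevelSolution(**d) for d in payload["levels"]],
        amplitudes={int(k): np.asarray(v) for k, v in payload["amplitudes"].items()},
        memory_amplitudes={
            int(k): np.asarray(v) for k, v in payload["memory_amplitudes"].items()
        },
        schedule=schedule,
    )


def pattern_to_json(pattern: HierarchicalPattern, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({"L": pattern.L, "bumps": pattern.to_records()}))
    return path


def pattern_from_json(path: str | Path) -> HierarchicalPattern:
    payload = json.loads(Path(path).read_text())
    return HierarchicalPattern.from_records(payload["bumps"], payload["L"])


def pattern_to_csv(pattern: HierarchicalPattern, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(pattern.to_records()).to_csv(path, index=False, float_format="%.17g")
    return path
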