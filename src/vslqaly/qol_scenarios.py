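"""Lifetime quality-of-life trajectories H_m(a) and the equal-area constraint.

Four built-in scenarios describe stylised health histories:

* ``SCN1`` — general ageing: QoL falls 2% a year after age 50.
* ``SCN2`` — gradual ageing: QoL falls 1% a year after age 50.
* ``SCN3`` — early deterioration: 1% a year from age 30, stable between 50
  and 70, then 1% a year again.
* ``SCN4`` — sudden event: QoL drops sharply at age 60 (default to 0.75 of
  full health), then falls 1% a year.

SCN2–SCN4 are adjusted to SCN1's lifetime QoL area by solving for the age at
which QoL is forced to 0, so the total life-extension effect is identical
across scenarios by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ScenarioSpec",
    "QoLTrajectory",
    "build_trajectory",
    "trajectory_area",
    "solve_terminal_age",
    "scenario_preset",
    "build_scenarios",
    "InfeasibleSpecError",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = ("SCN1", "SCN2", "SCN3", "SCN4")

DEFAULT_A_MAX = 110
DEFAULT_SHOCK_LEVEL = 0.75  # SCN4 post-shock QoL; equal-area feasibility needs > ~0.64


class InfeasibleSpecError(ValueError):
    """The untruncated trajectory's area is below the requested target area."""


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative QoL scenario.

    ``segments`` is an ordered tuple of ``(start_age, annual_decline_rate)``
    pairs; each rate applies from its start age until the next segment
    begins (a zero rate encodes a plateau). ``shock`` optionally forces H to
    ``post_shock_level`` at the shock age. ``decline_mode`` selects
    multiplicative decline ``H(a+1) = H(a) * (1 - rate)`` or linear decline
    ``H(a+1) = H(a) - rate``. ``terminal_age`` (possibly fractional) forces
    H to 0 at and beyond that age; ``None`` means untruncated.
    """

    name: str
    segments: tuple = ()
    shock: tuple | None = None
    decline_mode: str = "multiplicative"
    terminal_age: float | None = None
    a_max: int = DEFAULT_A_MAX

    def __post_init__(self):
        starts = [s for s, _ in self.segments]
        if sorted(starts) != starts or len(set(starts)) != len(starts):
            raise ValueError("segment start ages must be strictly increasing")
        if any(r < 0 for _, r in self.segments):
            raise ValueError("decline rates must be >= 0")
        if self.shock is not None and not (0 < self.shock[1] <= 1):
            raise ValueError("post-shock level must lie in (0, 1]")
        if self.terminal_age is not None and self.terminal_age > self.a_max:
            raise ValueError("terminal_age cannot exceed a_max")
        if self.decline_mode not in ("multiplicative", "linear"):
            raise ValueError(f"unknown decline_mode {self.decline_mode!r}")


@dataclass(frozen=True)
class QoLTrajectory:
    """H(a) on the integer grid 0..a_max.

    ``values`` is the trajectory actually used downstream (0 at and beyond
    any terminal age); ``untruncated`` keeps the pre-truncation recursion so
    the fractional-terminal-age area can be evaluated exactly on the linear
    interpolant.
    """

    name: str
    ages: np.ndarray
    values: np.ndarray
    untruncated: np.ndarray
    terminal_age: float | None = None

    @property
    def area(self) -> float:
        return trajectory_area(self)

    def at(self, a: float) -> float:
        """H at an integer age (0 at/past the terminal age)."""
        if self.terminal_age is not None and a >= self.terminal_age:
            return 0.0
        return float(np.interp(a, self.ages, self.untruncated))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"age": self.ages.astype(int), "H": self.values})


def build_trajectory(spec: ScenarioSpec) -> QoLTrajectory:
    """Run the annual decline recursion and apply shock/truncation rules."""
    ages = np.arange(0, spec.a_max + 1, dtype=float)
    h = np.ones_like(ages)
    for i in range(1, len(ages)):
        a_prev = ages[i - 1]
        rate = 0.0
        for s, r in spec.segments:
            if a_prev >= s:
                rate = r
        if spec.decline_mode == "multiplicative":
            h[i] = h[i - 1] * (1.0 - rate)
        else:
            h[i] = h[i - 1] - rate
        if spec.shock is not None and ages[i] == spec.shock[0]:
            if spec.shock[1] > h[i]:
                raise ValueError(
                    f"shock level {spec.shock[1]} exceeds current H {h[i]:.4f} at age {ages[i]:.0f}"
                )
            h[i] = spec.shock[1]
    h = np.clip(h, 0.0, 1.0)
    values = h.copy()
    if spec.terminal_age is not None:
        values[ages >= spec.terminal_age] = 0.0
    return QoLTrajectory(spec.name, ages, values, h, spec.terminal_age)


def _truncated_area(ages: np.ndarray, h: np.ndarray, t_end: float) -> float:
    """Exact integral of the linear interpolant of h over [0, t_end]."""
    t_end = min(float(t_end), float(ages[-1]))
    k = int(np.floor(t_end))
    area = float(np.trapezoid(h[: k + 1], ages[: k + 1])) if k >= 1 else 0.0
    frac = t_end - k
    if frac > 0:
        h_end = float(np.interp(t_end, ages, h))
        area += frac * (h[k] + h_end) / 2.0
    return area


def trajectory_area(traj: QoLTrajectory) -> float:
    """Lifetime QoL area in QoL-years (trapezoid; exact at a fractional terminal age)."""
    t_end = traj.terminal_age if traj.terminal_age is not None else traj.ages[-1]
    return _truncated_area(traj.ages, traj.untruncated, t_end)


def solve_terminal_age(
    spec: ScenarioSpec, target_area: float, tolerance: float = 1e-6
) -> ScenarioSpec:
    """Solve for the truncation age matching ``target_area``, by bisection.

    The truncated area is continuous and non-decreasing in the truncation
    age, so a root exists whenever the untruncated area reaches the target.
    If the untruncated trajectory already meets the target (within
    tolerance) the spec is returned with its natural terminal age — the age
    at which H first reaches 0, or a_max if it never does.
    """
    base = build_trajectory(replace(spec, terminal_age=None))
    full_area = _truncated_area(base.ages, base.untruncated, base.ages[-1])
    if full_area < target_area - tolerance:
        raise InfeasibleSpecError(
            f"{spec.name}: untruncated area {full_area:.6f} < target {target_area:.6f}"
        )
    if abs(full_area - target_area) <= tolerance:
        zero = np.where(base.untruncated <= 0)[0]
        natural = float(base.ages[zero[0]]) if zero.size else float(spec.a_max)
        return replace(spec, terminal_age=natural)

    lo = spec.segments[0][0] if spec.segments else 0.0

    def gap(t):
        return _truncated_area(base.ages, base.untruncated, t) - target_area

    t_star = brentq(gap, lo, spec.a_max, xtol=1e-10)
    assert abs(gap(t_star)) <= tolerance
    return replace(spec, terminal_age=float(t_star))


def scenario_preset(
    name: str,
    decline_mode: str = "multiplicative",
    a_max: int = DEFAULT_A_MAX,
    shock_level: float = DEFAULT_SHOCK_LEVEL,
) -> ScenarioSpec:
    """Built-in scenario specs SCN1–SCN4 (terminal age unsolved)."""
    presets = {
        "SCN1": dict(segments=((50, 0.02),)),
        "SCN2": dict(segments=((50, 0.01),)),
        "SCN3": dict(segments=((30, 0.01), (50, 0.0), (70, 0.01))),
        "SCN4": dict(segments=((60, 0.01),), shock=(60, shock_level)),
    }
    if name not in presets:
        raise KeyError(f"unknown scenario preset {name!r}")
    return ScenarioSpec(name=name, decline_mode=decline_mode, a_max=a_max, **presets[name])


def build_scenarios(
    decline_mode: str = "multiplicative",
    a_max: int = DEFAULT_A_MAX,
    shock_level: float = DEFAULT_SHOCK_LEVEL,
    tolerance: float = 1e-6,
) -> dict[str, QoLTrajectory]:
    """All four scenarios with SCN2–SCN4 area-matched to SCN1."""
    # SCN1 is the reference: untruncated, its area is the common target.
    scn1 = build_trajectory(scenario_preset("SCN1", decline_mode, a_max, shock_level))
    target = scn1.area
    out = {"SCN1": scn1}
    for name in ("SCN2", "SCN3", "SCN4"):
        spec = scenario_preset(name, decline_mode, a_max, shock_level)
        out[name] = build_trajectory(solve_terminal_age(spec, target, tolerance))
    return out
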