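"""Discounted lifetime-value integrals: VSL, life-extension value, QALY money value.

The value of a statistical life at age ``a`` under scenario ``m`` is the
discounted expected flow of full income plus Φ-weighted full consumption
over remaining life,

    VSL_m(a) = ∫_a  D(t, a) (y^F(t) + Φ_m(z_m(t)) c^F(t)) S(t, a) dt ,

with D the discount kernel and S conditional survival. The life-extension
value replaces S by the unit-area survival increment S(t-1, a) - S(t, a):

    LEV_m(a) = ∫_a  D(t, a) (y^F + Φ_m c^F) (S(t-1, a) - S(t, a)) dt ,

and the monetary value of one quality-adjusted life year at age ``a`` is
QALY_m(a) = LEV_m(a) / H_m(a). Integrals are composite trapezoids on the
unit age grid (inputs are annual), truncated at the table's terminal age
where survival has vanished; an optional refinement factor interpolates the
integrand onto a finer grid for convergence checks.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economic_data import EconomicProfile, PopulationDistribution, SurvivalModel
from .preference import PreferenceModel, phi, composite_good
from .qol_scenarios import QoLTrajectory

__all__ = [
    "DiscountSpec",
    "ValuationResult",
    "discount_factor",
    "vsl_curve",
    "lev",
    "qaly_value",
    "population_weighted_qaly",
    "evaluate_scenario",
    "sensitivity_sweep",
    "UndefinedQALYError",
]


class UndefinedQALYError(ValueError):
    """QALY requested at an age past the scenario's terminal age (H = 0)."""


@dataclass(frozen=True)
class DiscountSpec:
    """Exponential e^{-r(t-a)} or hyperbolic 1/(1 + kappa (t-a)) discounting.

    Default rate r = 1%/year; the hyperbolic kappa defaults to the same 1%
    so the two kernels agree to first order near t = a.
    """

    kind: str = "exponential"
    rate: float = 0.01
    kappa: float = 0.01

    def __post_init__(self):
        if self.kind not in ("exponential", "hyperbolic"):
            raise ValueError(f"unknown discount kind {self.kind!r}")
        if self.rate < 0 or self.kappa < 0:
            raise ValueError("discount parameters must be >= 0")


def discount_factor(t, a, spec: DiscountSpec):
    """Discount factor D(t, a) for t >= a."""
    t = np.asarray(t, dtype=float)
    if np.any(t < a):
        raise ValueError("require t >= a in the discount factor")
    dt = t - a
    out = np.exp(-spec.rate * dt) if spec.kind == "exponential" else 1.0 / (1.0 + spec.kappa * dt)
    return out if out.ndim else float(out)


def _integrand_values(profile, pref, traj, refine: int = 1):
    """Per-age money flow v(t) = y^F + Φ_m(z_m) c^F, optionally on a refined grid."""
    ages = profile.ages
    v = profile.full_income + pref.phi_series(profile, traj) * profile.full_consumption
    if refine == 1:
        return ages, v
    fine = np.arange(ages[0], ages[-1] + 1e-12, 1.0 / refine)
    # refine the inputs, not the product: Φ is re-evaluated on interpolated z
    y = np.interp(fine, ages, profile.full_income)
    c = np.interp(fine, ages, profile.full_consumption)
    h = np.interp(fine, ages, traj.values)
    return fine, y + phi(h * c, pref.utility) * c


def vsl_curve(
    surv: SurvivalModel,
    profile: EconomicProfile,
    pref: PreferenceModel,
    traj: QoLTrajectory,
    disc: DiscountSpec,
    a: float,
    refine: int = 1,
):
    """Per-age VSL-year contributions and their sum, the VSL at age ``a``.

    Returns ``(grid, vsl_year, vsl)`` where ``vsl_year`` holds the trapezoid
    weight times the integrand at each grid age, so ``vsl_year.sum() == vsl``.
    """
    if not (0 <= a <= surv.terminal_age):
        raise ValueError("age outside the model grid")
    grid_all, v_all = _integrand_values(profile, pref, traj, refine)
    mask = grid_all >= a
    grid = grid_all[mask]
    g = discount_factor(grid, a, disc) * v_all[mask] * surv(grid, a)
    w = _trapezoid_weights(grid)
    vsl_year = w * g
    return grid, vsl_year, float(vsl_year.sum())


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    if grid.size < 2:
        return np.zeros_like(grid)
    w = np.empty_like(grid)
    steps = np.diff(grid)
    w[0] = steps[0] / 2
    w[-1] = steps[-1] / 2
    w[1:-1] = (steps[:-1] + steps[1:]) / 2
    return w


def lev(
    surv: SurvivalModel,
    profile: EconomicProfile,
    pref: PreferenceModel,
    traj: QoLTrajectory,
    disc: DiscountSpec,
    a: float,
    refine: int = 1,
) -> float:
    """Life-extension value at age ``a``, via the unit-area survival increment.

    The grid extends one year past the table's terminal age so the final
    increment S(t-1, a) - S(t, a) is fully captured; money and QoL values at
    that extra point repeat the terminal-age values. S(t-1, a) is 1 for
    t - 1 <= a.
    """
    if not (0 <= a <= surv.terminal_age):
        raise ValueError("age outside the model grid")
    grid_all, v_all = _integrand_values(profile, pref, traj, refine)
    mask = grid_all >= a
    step = 1.0 / refine
    ext = np.arange(grid_all[-1] + step, grid_all[-1] + 1.0 + 1e-12, step)
    grid = np.concatenate([grid_all[mask], ext])
    v = np.concatenate([v_all[mask], np.full(ext.shape, v_all[-1])])
    increment = surv.shifted(grid, a) - surv(grid, a)
    g = discount_factor(grid, a, disc) * v * increment
    return float(np.sum(_trapezoid_weights(grid) * g))


def qaly_value(lev_value: float, traj: QoLTrajectory, a: float) -> float:
    """Monetary value of one QALY at age ``a``: LEV_m(a) / H_m(a)."""
    h = traj.at(a)
    if h <= 0:
        raise UndefinedQALYError(
            f"{traj.name}: H({a:g}) = 0 (age beyond the scenario's terminal age)"
        )
    return lev_value / h


@dataclass(frozen=True)
class ValuationResult:
    """Per-age value curves for one scenario.

    ``qaly`` is NaN at ages past the scenario's terminal age (H = 0), where
    the QALY money value is undefined; ``support`` marks defined ages.
    """

    scenario: str
    ages: np.ndarray
    vsl_year: np.ndarray  # contributions to VSL at the anchor age
    vsl: np.ndarray  # VSL_m(a) per age
    lev: np.ndarray  # LEV_m(a) per age
    qaly: np.ndarray  # LEV/H, NaN outside support
    support: np.ndarray  # boolean, H > 0
    anchor_age: float
    fingerprint: str

    @property
    def total_vsl(self) -> float:
        """VSL at the anchor age (the sum of all its VSL-years)."""
        idx = int(np.searchsorted(self.ages, self.anchor_age))
        return float(self.vsl[idx])

    def vsl_year_sum(self, from_age: float = 20.0) -> float:
        """Alternative total: sum of anchor VSL-years from ``from_age`` on."""
        return float(self.vsl_year[self.ages >= from_age].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages.astype(int),
                "vsl_year": self.vsl_year,
                "vsl": self.vsl,
                "lev": self.lev,
                "qaly": self.qaly,
            }
        )


def _fingerprint(**parts) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return hashlib.sha256(np.ascontiguousarray(o).tobytes()).hexdigest()[:16]
        return repr(o)

    blob = json.dumps(parts, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def evaluate_scenario(
    surv: SurvivalModel,
    profile: EconomicProfile,
    pref: PreferenceModel,
    traj: QoLTrajectory,
    disc: DiscountSpec,
    anchor_age: float = 0.0,
) -> ValuationResult:
    """Full per-age valuation of one scenario (VSL, LEV, QALY curves)."""
    ages = profile.ages
    anchor_grid, anchor_years, _ = vsl_curve(surv, profile, pref, traj, disc, anchor_age)
    vsl_year = np.zeros_like(ages)
    vsl_year[np.searchsorted(ages, anchor_grid)] = anchor_years
    vsl_a = np.empty_like(ages)
    lev_a = np.empty_like(ages)
    qaly_a = np.full_like(ages, np.nan)
    support = traj.values > 0
    for i, a in enumerate(ages):
        vsl_a[i] = vsl_curve(surv, profile, pref, traj, disc, a)[2]
        lev_a[i] = lev(surv, profile, pref, traj, disc, a)
        if support[i]:
            qaly_a[i] = qaly_value(lev_a[i], traj, a)
    fp = _fingerprint(
        scenario=traj.name,
        utility=(pref.utility.form, pref.utility.eta, pref.utility.z0),
        coupling=pref.coupling,
        discount=(disc.kind, disc.rate, disc.kappa),
        anchor=anchor_age,
        lx=surv.table.lx,
        income=profile.full_income,
        consumption=profile.full_consumption,
        qol=traj.values,
    )
    return ValuationResult(
        traj.name, ages, vsl_year, vsl_a, lev_a, qaly_a, support, anchor_age, fp
    )


def population_weighted_qaly(
    result: ValuationResult,
    pop: PopulationDistribution,
    age_range: tuple[float, float | None] = (20.0, None),
) -> float:
    """Population-weighted average QALY value, Σ N_a QALY(a) / Σ N_a.

    Restricted to ``age_range`` (default: adult ages) intersected with the
    scenario's support (H > 0) and ages with positive population.
    """
    lo, hi = age_range
    hi = result.ages[-1] if hi is None else hi
    counts = np.interp(result.ages, pop.ages, pop.counts, left=0.0, right=0.0)
    mask = (result.ages >= lo) & (result.ages <= hi) & result.support & (counts > 0)
    if not mask.any():
        raise ValueError("no overlap between population, age range and scenario support")
    return float(np.sum(counts[mask] * result.qaly[mask]) / counts[mask].sum())


def sensitivity_sweep(base_config, parameter: str, values) -> pd.DataFrame:
    """Re-run the full study for each parameter value; tidy results table.

    ``parameter`` is one of ``r``, ``kappa``, ``eta``, ``utility_form``,
    ``a_max``, ``shock_level``. Delegates to the study runner.
    """
    from . import pipeline  # runtime import: pipeline builds on this module

    return pipeline.sweep(base_config, parameter, values)
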