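"""Utility family, the composite good z(t), and the elasticity weight Φ.

The valuation integrand weights full consumption by

    Φ(z) = u(z) / (z u'(z)) - 1,

the elasticity term that converts consumption–leisure utility into money.
z(t) is the composite consumption–leisure good; quality of life enters by
scaling it, so poorer health lowers z, hence Φ, hence the consumption term
of the value of remaining life. Utilities are evaluated on the
non-dimensional ratio s = z / z0, where z0 is a reference scale calibrated
once per dataset (see ``vslqaly.pipeline.calibrate_reference_scale``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .economic_data import EconomicProfile
from .qol_scenarios import QoLTrajectory

__all__ = ["UtilityFamily", "PreferenceModel", "composite_good", "phi", "PHI_FLOOR"]

# Floor on Φ: the consumption term y^F + Φ c^F never falls below y^F - c^F,
# and Φ stays bounded/continuous in the H -> 0 limit where z -> 0.
PHI_FLOOR = -1.0


@dataclass(frozen=True)
class UtilityFamily:
    """CRRA or logarithmic utility of the composite good.

    ``eta`` is the coefficient of relative risk aversion (CRRA only; log is
    the eta -> 1 limit). ``z0`` is the reference scale in composite-good
    units (million JPY per year by default).
    """

    form: str = "crra"
    eta: float = 0.8
    z0: float = 1.0

    def __post_init__(self):
        if self.form not in ("log", "crra"):
            raise ValueError(f"unknown utility form {self.form!r}")
        if self.form == "crra" and (self.eta < 0 or self.eta == 1.0):
            raise ValueError("crra requires eta >= 0 and eta != 1 (use form='log')")
        if self.z0 <= 0:
            raise ValueError("z0 must be positive")


def phi(z, utility: UtilityFamily, floor: float | None = PHI_FLOOR):
    """Elasticity weight Φ(z) = u/(z u') - 1 evaluated at s = z / z0.

    log:   Φ = ln s - 1
    crra:  Φ = (1 - s^(eta-1)) / (1 - eta) - 1

    z = 0 returns the floor. Pass ``floor=None`` for the raw, unclipped
    family (used when studying Φ itself; the valuation always clips).
    """
    scalar = np.isscalar(z) or np.ndim(z) == 0
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if np.any(z < 0):
        raise ValueError("composite good must be non-negative")
    s = z / utility.z0
    out = np.full(s.shape, PHI_FLOOR if floor is None else floor, dtype=float)
    pos = s > 0
    with np.errstate(divide="ignore"):
        if utility.form == "log":
            out[pos] = np.log(s[pos]) - 1.0
        else:
            out[pos] = (1.0 - s[pos] ** (utility.eta - 1.0)) / (1.0 - utility.eta) - 1.0
    if floor is not None:
        out = np.maximum(out, floor)
    return float(out[0]) if scalar else out


def composite_good(
    profile: EconomicProfile, traj: QoLTrajectory, coupling: str = "multiplicative"
) -> np.ndarray:
    """Scenario composite good z_m(t).

    Default coupling scales full consumption by quality of life,
    z_m(t) = H_m(t) c^F(t): full consumption already bundles consumption and
    leisure, and H scales how much of it is enjoyed.
    """
    if profile.ages.shape != traj.ages.shape or np.any(profile.ages != traj.ages):
        raise ValueError("profile and trajectory must share the age grid")
    if coupling != "multiplicative":
        raise ValueError(f"unknown coupling rule {coupling!r}")
    return traj.values * profile.full_consumption


@dataclass(frozen=True)
class PreferenceModel:
    """Utility family plus the QoL-to-composite-good coupling rule."""

    utility: UtilityFamily = UtilityFamily()
    coupling: str = "multiplicative"

    def phi_series(self, profile: EconomicProfile, traj: QoLTrajectory) -> np.ndarray:
        """Per-age Φ_m(z_m(t)) on the common grid."""
        return phi(composite_good(profile, traj, self.coupling), self.utility)

    def with_scale(self, z0: float) -> "PreferenceModel":
        return PreferenceModel(
            UtilityFamily(self.utility.form, self.utility.eta, z0), self.coupling
        )
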