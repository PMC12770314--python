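"""Seeded synthetic socioeconomic inputs with the shape of aggregate Japanese data.

Real runs of this package consume public statistics (complete life tables,
wage-structure and household-consumption surveys, population by age). This
module generates stand-ins with the same statistical shape so the whole
pipeline is exercisable offline:

* mortality follows a Gompertz–Makeham hazard μ(x) = A + B e^{Cx}, giving a
  survival curve that is near 1 through mid-life and essentially 0 by age
  110 (life expectancy ≈ 86 years at the defaults, with substantial
  survival past 90, as in recent Japanese complete life tables);
* full income is a hump peaking in the late 40s and tapering smoothly to
  zero through retirement;
* full consumption is flatter and positive at every age: a mid-life bump
  around the peak-earnings years, and a rise at very old ages where the
  imputed value of non-market (leisure) time dominates the bundle — the
  hallmark of Murphy–Topel-style *full* consumption, which does not fall
  with retirement the way market spending does;
* the population pyramid is a mixture of cohort bumps emulating a
  super-aged population.

The curves are deterministic given the parameters; the seed only drives
optional multiplicative noise used to test reader robustness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .economic_data import EconomicProfile, LifeTable, PopulationDistribution

__all__ = [
    "SynthConfig",
    "generate_life_table",
    "generate_profiles",
    "generate_population",
    "japan_like",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic generator (defaults are the japan-like preset)."""

    seed: int = 0
    a_max: int = 110
    # Gompertz–Makeham hazard μ(x) = makeham_a + gompertz_b * exp(gompertz_c * x)
    makeham_a: float = 2e-4
    gompertz_b: float = 2.5e-6
    gompertz_c: float = 0.117
    # full-income hump (million JPY / year)
    wage_entry_age: float = 18.0
    wage_peak_age: float = 47.0
    wage_peak_level: float = 2.5
    wage_shape: float = 2.2  # larger = narrower hump
    retirement_start: float = 60.0
    retirement_end: float = 75.0
    # full consumption (million JPY / year)
    consumption_base: float = 2.5
    consumption_bump: float = 1.6
    consumption_bump_age: float = 50.0
    consumption_bump_width: float = 12.0
    # signed old-age shift: leisure-time value raises full consumption late in life
    consumption_oldage_shift: float = 1.4
    oldage_shift_start: float = 92.0
    oldage_shift_end: float = 108.0
    # population pyramid: (modal age, width, weight) bumps
    pyramid_modes: tuple = ((20.0, 14.0, 0.13), (52.0, 11.0, 0.29), (80.0, 9.0, 0.58))
    noise_sd: float = 0.0

    def __post_init__(self):
        if min(self.makeham_a, self.gompertz_b, self.gompertz_c) < 0:
            raise ValueError("mortality parameters must be >= 0")
        if self.wage_peak_level <= 0 or self.consumption_base <= 0:
            raise ValueError("monetary levels must be positive")


def japan_like(seed: int = 0) -> SynthConfig:
    """The shipped preset emulating aggregate Japanese inputs."""
    return SynthConfig(seed=seed)


def generate_life_table(cfg: SynthConfig) -> LifeTable:
    """Survival from the Gompertz–Makeham hazard, l(x) = exp(-∫_0^x μ).

    The cumulative hazard has the closed form A x + (B/C)(e^{Cx} - 1)
    (B x in the C -> 0 limit), so the table is exact and deterministic.
    """
    x = np.arange(0, cfg.a_max + 1, dtype=float)
    if cfg.gompertz_c > 0:
        cum = cfg.makeham_a * x + (cfg.gompertz_b / cfg.gompertz_c) * (
            np.exp(cfg.gompertz_c * x) - 1.0
        )
    else:
        cum = (cfg.makeham_a + cfg.gompertz_b) * x
    lx = np.exp(-cum)
    if lx[-1] > 1e-3:
        warnings.warn(
            f"l({cfg.a_max}) = {lx[-1]:.2e} > 1e-3: mortality tail not closed",
            stacklevel=2,
        )
    return LifeTable(x, lx, cfg.a_max)


def _smoothstep_down(x, start, end):
    """1 before start, 0 after end, C1-smooth in between."""
    t = np.clip((np.asarray(x, dtype=float) - start) / (end - start), 0.0, 1.0)
    return 1.0 - t * t * (3.0 - 2.0 * t)


def generate_profiles(cfg: SynthConfig) -> EconomicProfile:
    """Full-income hump and full-consumption curve on the unit age grid."""
    a = np.arange(0, cfg.a_max + 1, dtype=float)
    x = np.clip(
        (a - cfg.wage_entry_age) / (cfg.wage_peak_age - cfg.wage_entry_age), 0.0, None
    )
    k = cfg.wage_shape
    hump = np.where(x > 0, x**k * np.exp(k * (1.0 - x)), 0.0)  # gamma-shaped, peak 1 at x=1
    income = cfg.wage_peak_level * hump * _smoothstep_down(
        a, cfg.retirement_start, cfg.retirement_end
    )
    consumption = (
        cfg.consumption_base
        + cfg.consumption_bump
        * np.exp(-(((a - cfg.consumption_bump_age) / cfg.consumption_bump_width) ** 2))
        + cfg.consumption_oldage_shift
        * (1.0 - _smoothstep_down(a, cfg.oldage_shift_start, cfg.oldage_shift_end))
    )
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        income = np.clip(income * (1 + cfg.noise_sd * rng.standard_normal(a.size)), 0, None)
        consumption = np.clip(
            consumption * (1 + cfg.noise_sd * rng.standard_normal(a.size)), 1e-9, None
        )
    income[a >= cfg.retirement_end] = 0.0
    return EconomicProfile(a, income, consumption)


def generate_population(cfg: SynthConfig, total: float = 125_000_000) -> PopulationDistribution:
    """Mixture-of-bumps pyramid normalised to ``total`` persons.

    Counts are rounded to integers; the rounding residual is assigned to the
    modal age so the total is conserved exactly.
    """
    if total <= 0:
        raise ValueError("total population must be positive")
    a = np.arange(0, cfg.a_max + 1, dtype=float)
    density = np.zeros_like(a)
    for mode, width, weight in cfg.pyramid_modes:
        density += weight * np.exp(-0.5 * ((a - mode) / width) ** 2)
    # nobody alive at extreme old age regardless of the bump tails
    lt = generate_life_table(cfg)
    density *= lt.lx / lt.lx[0]
    density /= density.sum()
    counts = np.floor(density * total)
    residual = int(round(total - counts.sum()))
    counts[int(np.argmax(counts))] += residual
    return PopulationDistribution(a, counts)
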