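"""Scenario mixing and population-level cost-reduction evaluation.

Healthcare budgeting conventionally prices one QALY at a fixed benchmark
(5 million JPY in Japan). Given age- and scenario-specific QALY values
QALY_m(a) and scenario proportions β_m, the budget gap of pricing at the
benchmark instead is

    Cost Reduction = Σ_a N_a ( QALY_base − Σ_m β_m QALY_m(a) ) ,

positive = budget excess (the benchmark overpays), negative = insufficiency.
Inputs are in million JPY; the result is reported in trillion JPY.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economic_data import PopulationDistribution
from .valuation import ValuationResult

__all__ = [
    "PolicyConfig",
    "mix_scenarios",
    "cost_reduction",
    "case_table",
    "POLICY_CASES",
]

MILLION_PER_TRILLION = 1e6

# The five scenario-proportion cases of the published policy comparison,
# in percent (SCN1, SCN2, SCN3, SCN4).
POLICY_CASES = (
    ("case1", (100, 0, 0, 0)),
    ("case2", (70, 0, 15, 15)),
    ("case3", (50, 20, 15, 15)),
    ("case4", (30, 40, 15, 15)),
    ("case5", (10, 60, 15, 15)),
)


def _validate_weights(proportions, n=None) -> np.ndarray:
    beta = np.asarray(proportions, dtype=float)
    if n is not None and beta.size != n:
        raise ValueError(f"expected {n} proportions, got {beta.size}")
    if np.any(beta < 0):
        raise ValueError("scenario proportions must be >= 0")
    if beta.sum() > 1.0 + 1e-9:  # percent convention
        beta = beta / 100.0
    if abs(beta.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1 (got {beta.sum():.6g})")
    return beta


@dataclass(frozen=True)
class PolicyConfig:
    """Benchmark QALY price and scenario proportions β_m.

    ``qaly_base`` is in million JPY per QALY. Proportions may be given in
    percent; they are normalised to fractions and must sum to one.
    """

    qaly_base: float = 5.0
    proportions: tuple = (1.0, 0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.qaly_base <= 0:
            raise ValueError("qaly_base must be positive")
        object.__setattr__(
            self, "proportions", tuple(_validate_weights(self.proportions))
        )


def mix_scenarios(values, proportions) -> float:
    """Proportion-weighted mix Σ_m β_m value_m (full precision; round only for display)."""
    values = np.asarray(values, dtype=float)
    beta = _validate_weights(proportions, n=values.size)
    return float(np.sum(beta * values))


def cost_reduction(
    results: dict[str, ValuationResult],
    pop: PopulationDistribution,
    cfg: PolicyConfig,
    age_range: tuple[float, float | None] = (20.0, None),
) -> float:
    """Population cost reduction in trillion JPY.

    The age sum runs over the adult population by default (ages 20 and up,
    matching the age range over which the QALY curves are reported and
    population-weighted), restricted to ages with positive population and to
    the common support (H > 0) of every scenario with positive weight; ages
    past a weighted scenario's terminal age are excluded because its QALY is
    undefined there.
    """
    names = sorted(results)
    beta = _validate_weights(cfg.proportions, n=len(names))
    ref = results[names[0]]
    counts = np.interp(ref.ages, pop.ages, pop.counts, left=0.0, right=0.0)
    lo, hi = age_range
    hi = ref.ages[-1] if hi is None else hi
    mask = (counts > 0) & (ref.ages >= lo) & (ref.ages <= hi)
    for name, b in zip(names, beta):
        if b > 0:
            mask &= results[name].support
    if not mask.any():
        raise ValueError("no ages with population inside every weighted scenario's support")
    mixed = np.zeros(mask.sum())
    for name, b in zip(names, beta):
        if b > 0:
            mixed += b * results[name].qaly[mask]
    total_million = float(np.sum(counts[mask] * (cfg.qaly_base - mixed)))
    return total_million / MILLION_PER_TRILLION


def case_table(
    cases,
    results: dict[str, ValuationResult],
    pop: PopulationDistribution,
    qaly_base: float = 5.0,
    age_range: tuple[float, float | None] = (20.0, None),
) -> pd.DataFrame:
    """Cost reduction for each (case_id, proportions) row, in trillion JPY."""
    names = sorted(results)
    rows = []
    for case_id, props in cases:
        try:
            cfg = PolicyConfig(qaly_base=qaly_base, proportions=tuple(props))
            cr = cost_reduction(results, pop, cfg, age_range)
        except ValueError as exc:
            raise ValueError(f"case {case_id!r}: {exc}") from exc
        row = {"case": case_id}
        row.update({f"pct_{n}": 100 * b for n, b in zip(names, cfg.proportions)})
        row["cost_reduction_trillion_jpy"] = cr
        rows.append(row)
    return pd.DataFrame(rows)


def read_case_file(path) -> list[tuple[str, tuple]]:
    """Read a case CSV with columns case_id, SCN1..SCN4 (proportions in percent)."""
    df = pd.read_csv(path)
    if "case_id" not in df.columns:
        raise ValueError("case file needs a case_id column")
    scn_cols = [c for c in df.columns if c != "case_id"]
    return [
        (str(row["case_id"]), tuple(float(row[c]) for c in scn_cols))
        for _, row in df.iterrows()
    ]
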