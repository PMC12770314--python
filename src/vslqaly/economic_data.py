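"""Age-indexed socioeconomic inputs: life tables, income/consumption profiles, population.

All monetary quantities are carried in million JPY per year unless a profile
says otherwise via its ``currency_unit`` label. Age grids are integer years
``0 .. terminal_age`` after reading/interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "SurvivalModel",
    "EconomicProfile",
    "PopulationDistribution",
    "CsvDialect",
    "read_life_table",
    "read_age_profile",
    "survival",
    "ValidationError",
    "FormatError",
]


class ValidationError(ValueError):
    """An input table violates a structural invariant (named ages in message)."""


class FormatError(ValueError):
    """A CSV is missing required columns or has an unparseable layout."""


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping for the CSV readers.

    ``age_column`` may hold single integers or bands written ``"20-24"``
    (interpreted as inclusive). For life tables exactly one of
    ``survivors_column`` (l(x)) or ``deaths_column`` (q(x)) must be present
    in the file.
    """

    age_column: str = "age"
    value_column: str = "value"
    survivors_column: str = "l"
    deaths_column: str = "q"
    band_mode: str = "constant"  # constant | midpoint


@dataclass(frozen=True)
class LifeTable:
    """Period life table on a unit integer age grid.

    ``lx`` holds survivors l(x) with arbitrary radix (l(0) need not be 1);
    only ratios matter. l is non-increasing and treated as 0 beyond
    ``terminal_age``.
    """

    ages: np.ndarray
    lx: np.ndarray
    terminal_age: int

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        lx = np.asarray(self.lx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "lx", lx)
        if ages.shape != lx.shape or ages.ndim != 1:
            raise ValidationError("ages and lx must be 1-d arrays of equal length")
        if not np.all(np.diff(ages) == 1):
            raise ValidationError("ages must be strictly increasing with unit step")
        if np.any(lx < 0):
            raise ValidationError("survivor counts must be non-negative")
        bad = np.where(np.diff(lx) > 0)[0]
        if bad.size:
            raise ValidationError(
                f"l(x) increases at ages {ages[bad + 1].astype(int).tolist()}"
            )

    @classmethod
    def from_qx(cls, ages: np.ndarray, qx: np.ndarray, radix: float = 1.0) -> "LifeTable":
        """Build l(x) from one-year death probabilities by recursive product."""
        qx = np.asarray(qx, dtype=float)
        if np.any((qx < 0) | (qx > 1)):
            raise ValidationError("q(x) must lie in [0, 1]")
        lx = radix * np.concatenate([[1.0], np.cumprod(1.0 - qx[:-1])])
        return cls(np.asarray(ages, dtype=float), lx, int(np.asarray(ages)[-1]))

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages.astype(int), "l": self.lx}).to_csv(path, index=False)


def _expand_bands(raw_ages: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Parse an age column of ints or "lo-hi" bands into (lows, highs)."""
    lows, highs = [], []
    for v in raw_ages:
        s = str(v).strip()
        if "-" in s and not s.lstrip().startswith("-"):
            lo, hi = s.split("-", 1)
            lows.append(int(lo))
            highs.append(int(hi))
        else:
            lows.append(int(float(s)))
            highs.append(int(float(s)))
    return np.array(lows), np.array(highs)


def read_life_table(path, dialect: CsvDialect | None = None) -> LifeTable:
    """Read a life table CSV holding either l(x) or q(x).

    Ages must be single integers (life tables are published on unit grids);
    missing intermediate ages are filled by linear interpolation of l.
    """
    dialect = dialect or CsvDialect()
    df = pd.read_csv(path)
    if dialect.age_column not in df.columns:
        raise FormatError(f"missing age column {dialect.age_column!r}")
    has_l = dialect.survivors_column in df.columns
    has_q = dialect.deaths_column in df.columns
    if not (has_l or has_q):
        raise FormatError(
            f"need column {dialect.survivors_column!r} (l) or {dialect.deaths_column!r} (q)"
        )
    ages = df[dialect.age_column].to_numpy(dtype=float)
    if has_l:
        lx = df[dialect.survivors_column].to_numpy(dtype=float)
    else:
        return LifeTable.from_qx(ages, df[dialect.deaths_column].to_numpy(dtype=float))
    full = np.arange(ages[0], ages[-1] + 1)
    lx_full = np.interp(full, ages, lx)
    return LifeTable(full, lx_full, int(full[-1]))


def survival(table: LifeTable, t, a) -> float | np.ndarray:
    """Conditional survival S(t, a) = l(t)/l(a), l linearly interpolated.

    Returns 0 beyond the terminal age and wherever l(a) = 0. ``t`` may be an
    array; ``a`` is a scalar with ``t >= a`` required.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < a):
        raise ValueError("require t >= a in S(t, a)")
    la = float(np.interp(a, table.ages, table.lx, left=0.0, right=0.0))
    if la == 0.0:
        out = np.zeros_like(t)
        return out if out.ndim else 0.0
    lt = np.interp(t, table.ages, table.lx, left=0.0, right=0.0)
    out = lt / la
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SurvivalModel:
    """Callable wrapper around a LifeTable exposing S(t, a).

    Invariants: S(a, a) = 1, S non-increasing in t, S = 0 past the terminal
    age. ``shifted(t, a)`` evaluates S(t-1, a) with the convention that it is
    1 for t - 1 <= a (one cannot have died before the conditioning age).
    """

    table: LifeTable

    @property
    def terminal_age(self) -> int:
        return self.table.terminal_age

    def __call__(self, t, a):
        return survival(self.table, t, a)

    def curve(self, a: float, grid=None) -> np.ndarray:
        grid = np.arange(a, self.terminal_age + 1) if grid is None else np.asarray(grid)
        return survival(self.table, grid, a)

    def shifted(self, t, a):
        t = np.asarray(t, dtype=float)
        out = np.where(t - 1.0 <= a, 1.0, survival(self.table, np.maximum(t - 1.0, a), a))
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class EconomicProfile:
    """Full income y^F(t) and full consumption c^F(t) on a unit age grid."""

    ages: np.ndarray
    full_income: np.ndarray
    full_consumption: np.ndarray
    currency_unit: str = "million JPY"

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        y = np.asarray(self.full_income, dtype=float)
        c = np.asarray(self.full_consumption, dtype=float)
        for name, arr in (("full_income", y), ("full_consumption", c)):
            if arr.shape != ages.shape:
                raise ValidationError(f"{name} must match the age grid")
            if np.any(~np.isfinite(arr)) or np.any(arr < 0):
                raise ValidationError(f"{name} must be finite and non-negative")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "full_income", y)
        object.__setattr__(self, "full_consumption", c)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages.astype(int),
                "full_income": self.full_income,
                "full_consumption": self.full_consumption,
            }
        )


def read_age_profile(
    path,
    column: str | None = None,
    *,
    kind: str = "income",
    a_max: int = 110,
    dialect: CsvDialect | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Read one age-banded money column and expand it to a unit grid 0..a_max.

    Band expansion is constant-within-band by default; ``dialect.band_mode
    == "midpoint"`` instead places each band's value at its midpoint and
    interpolates linearly between midpoints. Ages past the last observed
    band extrapolate to 0 for ``kind="income"`` and to the last observed
    value for ``kind="consumption"``; ages before the first band are 0 for
    income and first-observed for consumption.
    """
    dialect = dialect or CsvDialect()
    col = column or dialect.value_column
    df = pd.read_csv(path)
    if dialect.age_column not in df.columns or col not in df.columns:
        raise FormatError(f"need columns {dialect.age_column!r} and {col!r}")
    vals = df[col].to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValidationError(f"negative monetary values in column {col!r}")
    lows, highs = _expand_bands(df[dialect.age_column])
    order = np.argsort(lows)
    lows, highs, vals = lows[order], highs[order], vals[order]

    grid = np.arange(0, a_max + 1)
    out = np.full(grid.shape, np.nan)
    if dialect.band_mode == "midpoint":
        mids = (lows + highs) / 2.0
        inside = (grid >= lows[0]) & (grid <= highs[-1])
        out[inside] = np.interp(grid[inside], mids, vals)
    elif dialect.band_mode == "constant":
        for lo, hi, v in zip(lows, highs, vals):
            out[(grid >= lo) & (grid <= hi)] = v
        # unlisted ages inside the observed range take the previous band's value
        inside = (grid >= lows[0]) & (grid <= highs[-1])
        idx = np.searchsorted(lows, grid[inside], side="right") - 1
        fill = vals[np.clip(idx, 0, len(vals) - 1)]
        out[inside] = np.where(np.isnan(out[inside]), fill, out[inside])
    else:
        raise FormatError(f"unknown band_mode {dialect.band_mode!r}")

    if kind == "income":
        out[grid < lows[0]] = 0.0
        out[grid > highs[-1]] = 0.0
    elif kind == "consumption":
        out[grid < lows[0]] = vals[0]
        out[grid > highs[-1]] = vals[-1]
    else:
        raise ValueError(f"unknown profile kind {kind!r}")
    return grid.astype(float), out


@dataclass(frozen=True)
class PopulationDistribution:
    """Population counts N_a by single year of age."""

    ages: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != ages.shape:
            raise ValidationError("counts must match the age grid")
        if np.any(counts < 0):
            raise ValidationError("population counts must be non-negative")
        if not np.any(counts > 0):
            raise ValidationError("population must contain at least one positive count")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def mean_age(self) -> float:
        return float(np.sum(self.ages * self.counts) / self.counts.sum())

    @classmethod
    def read_csv(cls, path, dialect: CsvDialect | None = None) -> "PopulationDistribution":
        dialect = dialect or CsvDialect()
        df = pd.read_csv(path)
        age_col = dialect.age_column
        count_col = "count" if "count" in df.columns else dialect.value_column
        if age_col not in df.columns or count_col not in df.columns:
            raise FormatError(f"need columns {age_col!r} and {count_col!r}")
        return cls(df[age_col].to_numpy(float), df[count_col].to_numpy(float))

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages.astype(int), "count": self.counts}).to_csv(
            path, index=False
        )
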