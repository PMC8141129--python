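"""Background (non-diabetic) mortality.

The model takes the annual death probability ``qx`` of people without
diabetes from a period life table and scales it, on the hazard scale, by the
state-specific mortality relative risks of the disease model.  Because no
national table ships with the package, :func:`make_gompertz_lifetable`
generates a parametric Gompertz–Makeham stand-in whose defaults are tuned to
resemble a high-income-country table (they are synthetic, not any official
table).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError

__all__ = [
    "LifeTable",
    "read_life_table",
    "write_life_table",
    "make_gompertz_lifetable",
    "life_expectancy",
    "adjusted_mortality",
    "GOMPERTZ_DEFAULTS",
]

#: Synthetic Gompertz–Makeham defaults (baseline hazard a, log-hazard slope b,
#: Makeham constant c, terminal age).  Chosen to give a life expectancy at age
#: 30 of roughly 51 further years; explicitly NOT an official national table.
GOMPERTZ_DEFAULTS = {"a": 2e-5, "b": 0.1, "c": 5e-4, "max_age": 110}


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities ``qx`` on contiguous integer ages."""

    min_age: int
    qx: np.ndarray  # qx[i] is the death probability at age min_age + i

    def __post_init__(self) -> None:
        q = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "qx", q)
        if q.ndim != 1 or q.size < 1:
            raise ValidationError("life table needs a 1-D, non-empty qx array")
        if np.any((q < 0) | (q > 1)):
            raise ValidationError("every qx must be in [0,1]")
        if q[-1] != 1.0:
            raise ValidationError(f"qx at the terminal age must be 1, got {q[-1]}")

    @property
    def max_age(self) -> int:
        return self.min_age + self.qx.size - 1

    def qx_at(self, age: int | np.ndarray) -> float | np.ndarray:
        idx = np.asarray(age) - self.min_age
        if np.any(idx < 0) or np.any(idx >= self.qx.size):
            raise DomainError(f"age outside life-table range [{self.min_age}, {self.max_age}]")
        return self.qx[idx]


def read_life_table(path: str | Path) -> LifeTable:
    """Read an ``age,qx`` CSV into a :class:`LifeTable`.

    Ages must be contiguous integers; if the final qx is not 1 it is coerced
    to 1 (the table must close the cohort) and a notice is printed.
    """
    df = pd.read_csv(path)
    if list(df.columns) != ["age", "qx"]:
        raise ValidationError(f"life-table CSV must have header 'age,qx', got {list(df.columns)}")
    ages = df["age"].to_numpy()
    if not np.array_equal(ages, ages.astype(int)):
        raise ValidationError("ages must be integers")
    ages = ages.astype(int)
    expected = np.arange(ages[0], ages[0] + ages.size)
    if not np.array_equal(ages, expected):
        missing = sorted(set(expected) - set(ages))
        raise ValidationError(f"ages must be contiguous; missing age(s) {missing[:5]}")
    qx = df["qx"].to_numpy(dtype=float)
    if np.any((qx < 0) | (qx > 1)):
        bad = int(ages[np.argmax((qx < 0) | (qx > 1))])
        raise ValidationError(f"qx outside [0,1] at age {bad}")
    if qx[-1] != 1.0:
        print(f"note: coercing qx at terminal age {ages[-1]} from {qx[-1]} to 1")
        qx = qx.copy()
        qx[-1] = 1.0
    return LifeTable(min_age=int(ages[0]), qx=qx)


def write_life_table(lt: LifeTable, path: str | Path) -> None:
    ages = np.arange(lt.min_age, lt.max_age + 1)
    pd.DataFrame({"age": ages, "qx": lt.qx}).to_csv(path, index=False)


def make_gompertz_lifetable(a: float = GOMPERTZ_DEFAULTS["a"],
                            b: float = GOMPERTZ_DEFAULTS["b"],
                            c: float = GOMPERTZ_DEFAULTS["c"],
                            max_age: int = GOMPERTZ_DEFAULTS["max_age"],
                            min_age: int = 0) -> LifeTable:
    """Gompertz–Makeham life table: hazard(age) = c + a*exp(b*age).

    qx(age) = 1 - exp(-(c + a*exp(b*age))) for age < max_age and 1 at
    max_age, so the table always closes the cohort.
    """
    if a < 0 or b < 0 or c < 0:
        raise DomainError("Gompertz–Makeham parameters must be >= 0")
    if a == 0 and c == 0:
        raise DomainError("at least one of a, c must be positive")
    if max_age < 1:
        raise DomainError("max_age must be >= 1")
    ages = np.arange(min_age, max_age + 1)
    qx = 1.0 - np.exp(-(c + a * np.exp(b * ages)))
    qx = np.clip(qx, 0.0, 1.0)
    qx[-1] = 1.0
    return LifeTable(min_age=min_age, qx=qx)


def life_expectancy(lt: LifeTable, entry_age: int) -> float:
    """Remaining life expectancy at ``entry_age``: sum of survival
    probabilities S(t) = prod_{k<t} (1 - q_{entry_age+k})."""
    if not (lt.min_age <= entry_age <= lt.max_age):
        raise DomainError(f"entry_age {entry_age} outside table range")
    q = lt.qx[entry_age - lt.min_age:]
    surv = np.cumprod(1.0 - q)
    return float(surv.sum())


def adjusted_mortality(qx: float | np.ndarray, rr: float) -> float | np.ndarray:
    """Apply a mortality relative risk on the hazard scale: 1 - (1-qx)^rr.

    Unlike naive probability multiplication this stays in [0,1] for any
    rr > 0, equals qx at rr = 1 and 1 at qx = 1.
    """
    if rr <= 0:
        raise DomainError(f"relative risk must be > 0, got {rr}")
    q = np.asarray(qx, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise DomainError("qx must be in [0,1]")
    out = 1.0 - (1.0 - q) ** rr
    return float(out) if np.isscalar(qx) else out
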