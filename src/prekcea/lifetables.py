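"""Background mortality: life-table container, CSV loader, synthetic generator.

The simulation only needs an age-indexed schedule of annual death
probabilities ``qx``. Real tables (e.g. a national vital-statistics life
table) are read from a two-column CSV (``age``, ``qx``; one-year ages from
0). For download-free runs a deterministic synthetic table is generated from
a Gompertz hazard ``h(age) = a * exp(b * age)``, which gives the familiar
monotone-increasing adult mortality with a life expectancy tunable through
``a`` and ``b``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LifeTable", "load_life_table", "make_gompertz_lifetable", "life_expectancy"]


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities ``qx[age]`` for contiguous ages 0..max_age."""

    qx: np.ndarray  # shape (max_age + 1,)

    def __post_init__(self) -> None:
        q = np.asarray(self.qx, dtype=float)
        if q.ndim != 1 or q.size < 1:
            raise ValueError("qx must be a one-dimensional array of probabilities")
        if np.any(q < 0) or np.any(q > 1) or np.any(~np.isfinite(q)):
            raise ValueError("every qx must lie in [0, 1]")
        object.__setattr__(self, "qx", q)

    @property
    def max_age(self) -> int:
        return self.qx.size - 1

    def q(self, age: int) -> float:
        """Annual death probability at integer ``age``."""
        if not 0 <= age <= self.max_age:
            raise KeyError(f"age {age} outside table range 0..{self.max_age}")
        return float(self.qx[age])


def load_life_table(path: str | Path) -> LifeTable:
    """Load a life table from a CSV with columns ``age`` and ``qx``.

    Ages must be contiguous one-year ages starting at 0; probabilities must
    lie in [0, 1].
    """
    frame = pd.read_csv(path)
    missing = {"age", "qx"} - set(frame.columns)
    if missing:
        raise ValueError(f"life table {path} missing columns: {sorted(missing)}")
    ages = frame["age"].to_numpy()
    expected = np.arange(len(frame))
    if not np.array_equal(ages, expected):
        raise ValueError(
            f"life table ages must be contiguous 0..{len(frame) - 1}; got gaps or disorder"
        )
    return LifeTable(qx=frame["qx"].to_numpy(dtype=float))


def make_gompertz_lifetable(a: float = 1e-4, b: float = 0.085,
                            max_age: int = 105) -> LifeTable:
    """Deterministic synthetic life table from a Gompertz hazard.

    ``qx(age) = 1 - exp(-a * exp(b * age))``, capped at 1, with the terminal
    age forced to ``qx = 1`` so every simulated life ends. ``b = 0`` degrades
    to a constant (exponential) hazard. Defaults give a life expectancy at
    birth near 79 years.
    """
    if a <= 0:
        raise ValueError("baseline hazard a must be positive")
    if b < 0:
        raise ValueError("slope b must be nonnegative")
    ages = np.arange(max_age + 1)
    qx = 1.0 - np.exp(-a * np.exp(b * ages))
    qx = np.clip(qx, 0.0, 1.0)
    qx[max_age] = 1.0
    return LifeTable(qx=qx)


def life_expectancy(lt: LifeTable, from_age: int = 0,
                    half_cycle: bool = False) -> float:
    """Expected remaining whole years of life at ``from_age``.

    Standard cohort expectation ``sum_{t>=1} prod_{k<t} (1 - qx(from_age+k))``
    — the expected number of completed years, matching the simulation's
    life-year accounting. ``half_cycle=True`` adds the half-year correction
    (+0.5 expected fraction of the death year).
    """
    if not 0 <= from_age <= lt.max_age:
        raise ValueError(f"from_age {from_age} outside table range 0..{lt.max_age}")
    survival = np.cumprod(1.0 - lt.qx[from_age:])
    le = float(np.sum(survival))
    if half_cycle:
        le += 0.5
    return le
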