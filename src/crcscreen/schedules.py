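"""Age-indexed annual schedules (probabilities or costs).

Every epidemiological input to the model is either a scalar or an
:class:`AgeSchedule`: one value per integer year of age covering at least
ages 45 through 100. Schedules are immutable; derived schedules are built
with :meth:`AgeSchedule.map`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

AGE_MIN = 45
AGE_MAX = 100

_ROLES = ("probability", "cost")


@dataclass(frozen=True)
class AgeSchedule:
    """One value per integer age, covering at least 45..100.

    Parameters
    ----------
    ages : array-like of int
        Contiguous ascending integer ages; must span 45..100 inclusive.
    values : array-like of float
        Annual probability (in [0, 1]) or cost (USD, >= 0) per age.
    role : {"probability", "cost"}
        Validation regime applied to ``values``.
    """

    ages: np.ndarray
    values: np.ndarray
    role: str = "probability"

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if ages.ndim != 1 or values.ndim != 1 or ages.size != values.size:
            raise ValueError("ages and values must be 1-D arrays of equal length")
        if ages.size == 0 or np.any(np.diff(ages) != 1):
            raise ValueError("ages must be contiguous ascending integers")
        if ages[0] > AGE_MIN or ages[-1] < AGE_MAX:
            raise ValueError(
                f"schedule must cover ages {AGE_MIN}..{AGE_MAX}; got {ages[0]}..{ages[-1]}"
            )
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")
        if not np.all(np.isfinite(values)):
            raise ValueError("schedule values must be finite")
        if self.role == "probability":
            if np.any(values < 0.0) or np.any(values > 1.0):
                raise ValueError("probability-role values must lie in [0, 1]")
        else:
            if np.any(values < 0.0):
                raise ValueError("cost-role values must be >= 0")
        ages.setflags(write=False)
        values.setflags(write=False)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)

    def value(self, age: int) -> float:
        """Value at an integer ``age`` (must be within the covered range)."""
        idx = int(age) - int(self.ages[0])
        if idx < 0 or idx >= self.ages.size:
            raise KeyError(f"age {age} outside schedule range {self.ages[0]}..{self.ages[-1]}")
        return float(self.values[idx])

    __call__ = value

    def slice(self, lo: int = AGE_MIN, hi: int = AGE_MAX) -> np.ndarray:
        """Values for ages ``lo..hi`` inclusive, as an array."""
        i0 = lo - int(self.ages[0])
        return np.asarray(self.values[i0 : i0 + (hi - lo + 1)])

    def map(self, fn) -> "AgeSchedule":
        """Return a new schedule with ``fn`` applied elementwise to values."""
        return AgeSchedule(self.ages.copy(), fn(self.values.copy()), self.role)

    def scaled(self, factor: float) -> "AgeSchedule":
        out = self.values * factor
        if self.role == "probability":
            out = np.clip(out, 0.0, 1.0)
        return AgeSchedule(self.ages.copy(), out, self.role)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "value": self.values})

    def to_csv(self, path, params: dict | None = None) -> None:
        """Write ``age,value`` CSV plus a JSON sidecar naming the role."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {"role": self.role, "params": params or {}}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path) -> "AgeSchedule":
        path = Path(path)
        df = pd.read_csv(path)
        role = "probability"
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            role = json.loads(sidecar.read_text()).get("role", "probability")
        return cls(df["age"].to_numpy(), df["value"].to_numpy(), role)


def constant_schedule(value: float, role: str = "probability") -> AgeSchedule:
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    return AgeSchedule(ages, np.full(ages.size, float(value)), role)


def schedule_from_fn(fn, role: str = "probability") -> AgeSchedule:
    """Build a schedule by evaluating ``fn(age)`` on 45..100."""
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    return AgeSchedule(ages, np.array([float(fn(a)) for a in ages]), role)
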