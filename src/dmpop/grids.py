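"""Population state containers indexed by annual age class, sex and health status.

The demographic state is a grid of counts over 101 annual age classes
(0..100 completed years) and two sexes.  The disease overlay refines each
cell into three health statuses: healthy (H), undiagnosed diabetes (U) and
diagnosed diabetes (D).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N_AGES = 101
SEXES = ("female", "male")
STATUSES = ("H", "U", "D")

SEX_INDEX = {s: i for i, s in enumerate(SEXES)}
STATUS_INDEX = {s: i for i, s in enumerate(STATUSES)}


def _check_counts(counts: np.ndarray, shape: tuple, what: str) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if counts.shape != shape:
        raise ValueError(f"{what} counts must have shape {shape}, got {counts.shape}")
    if not np.all(np.isfinite(counts)):
        raise ValueError(f"{what} counts must be finite")
    if counts.min() < 0:
        raise ValueError(f"{what} counts must be nonnegative (min={counts.min():g})")
    return counts


@dataclass
class AgeSexGrid:
    """Counts per (age class 0..100, sex), at a calendar reference time."""

    counts: np.ndarray  # shape (101, 2): [age, sex], sex order (female, male)
    reference_time: float

    def __post_init__(self) -> None:
        self.counts = _check_counts(self.counts, (N_AGES, len(SEXES)), "AgeSexGrid")
        self.reference_time = float(self.reference_time)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def by_sex(self, sex: str) -> np.ndarray:
        return self.counts[:, SEX_INDEX[sex]]

    def mean_age(self) -> float:
        """Count-weighted mean age (class midpoints a + 0.5)."""
        ages = np.arange(N_AGES) + 0.5
        tot = self.counts.sum()
        if tot <= 0:
            raise ValueError("mean age undefined for an empty population")
        return float((ages @ self.counts.sum(axis=1)) / tot)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for si, sex in enumerate(SEXES):
            for a in range(N_AGES):
                rows.append((sex, a, self.counts[a, si]))
        return pd.DataFrame(rows, columns=["sex", "age", "count"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, reference_time: float) -> "AgeSexGrid":
        required = {"sex", "age", "count"}
        if not required.issubset(frame.columns):
            raise ValueError(f"census table must have columns {sorted(required)}")
        counts = np.full((N_AGES, len(SEXES)), np.nan)
        for _, row in frame.iterrows():
            sex = str(row["sex"])
            if sex not in SEX_INDEX:
                raise ValueError(f"unknown sex label {sex!r}")
            age = int(row["age"])
            if not 0 <= age < N_AGES:
                raise ValueError(f"age {age} outside 0..100")
            counts[age, SEX_INDEX[sex]] = float(row["count"])
        missing = np.argwhere(np.isnan(counts))
        if missing.size:
            a, si = missing[0]
            raise ValueError(f"missing census row for (sex={SEXES[si]}, age={a})")
        return cls(counts=counts, reference_time=reference_time)

    @classmethod
    def from_csv(cls, path, reference_time: float) -> "AgeSexGrid":
        return cls.from_frame(pd.read_csv(path), reference_time)


@dataclass
class HealthStateGrid:
    """Counts per (age class, sex, health status H/U/D)."""

    counts: np.ndarray  # shape (101, 2, 3): [age, sex, status]
    reference_time: float

    def __post_init__(self) -> None:
        self.counts = _check_counts(
            self.counts, (N_AGES, len(SEXES), len(STATUSES)), "HealthStateGrid"
        )
        self.reference_time = float(self.reference_time)

    def marginal(self) -> AgeSexGrid:
        """Age/sex population irrespective of health status."""
        return AgeSexGrid(self.counts.sum(axis=2), self.reference_time)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def status(self, status: str) -> np.ndarray:
        """(101, 2) counts for one health status."""
        return self.counts[:, :, STATUS_INDEX[status]]

    def status_totals(self) -> dict[str, float]:
        return {s: float(self.counts[:, :, i].sum()) for i, s in enumerate(STATUSES)}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for si, sex in enumerate(SEXES):
            for sti, st in enumerate(STATUSES):
                for a in range(N_AGES):
                    rows.append((sex, a, st, self.counts[a, si, sti]))
        return pd.DataFrame(rows, columns=["sex", "age", "status", "count"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, reference_time: float) -> "HealthStateGrid":
        counts = np.full((N_AGES, len(SEXES), len(STATUSES)), np.nan)
        for _, row in frame.iterrows():
            counts[int(row["age"]), SEX_INDEX[str(row["sex"])],
                   STATUS_INDEX[str(row["status"])]] = float(row["count"])
        if np.isnan(counts).any():
            raise ValueError("incomplete health-state table")
        return cls(counts=counts, reference_time=reference_time)

    @classmethod
    def from_csv(cls, path, reference_time: float) -> "HealthStateGrid":
        return cls.from_frame(pd.read_csv(path), reference_time)


def all_healthy(population: AgeSexGrid) -> HealthStateGrid:
    """Lift an age/sex grid to a health-state grid with everyone healthy."""
    counts = np.zeros((N_AGES, len(SEXES), len(STATUSES)))
    counts[:, :, 0] = population.counts
    return HealthStateGrid(counts=counts, reference_time=population.reference_time)
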