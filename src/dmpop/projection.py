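"""Posterior-sampled forward projection of the diabetes burden.

Parameter vectors are drawn (without replacement) from the pooled
post-burn-in chains; each draw drives one forward simulation from the
disease introduction year to the projection horizon.  Summaries are
quantiles over draws: counts of people with diabetes (diagnosed +
undiagnosed) per year, sex and age group, overall prevalence, the
undiagnosed share, and percent changes between named years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import DemographicSchedule, IntegratorOptions, ScheduleCoverageError
from .disease import ModelConfig, simulate_disease
from .grids import SEXES, HealthStateGrid
from .inference import PosteriorChains


def prevalence_percent(grid: HealthStateGrid, numerator_statuses=("U", "D"),
                       *, age_range: tuple[int, int] | None = None,
                       sex: str | None = None) -> float:
    """100 x (counts in numerator statuses) / (all statuses), optionally
    restricted by age range (inclusive) and sex."""
    from .grids import STATUS_INDEX

    counts = grid.counts
    if age_range is not None:
        counts = counts[age_range[0]:age_range[1] + 1]
    if sex is not None:
        counts = counts[:, [SEXES.index(sex)], :]
    total = counts.sum()
    if total <= 0:
        raise ValueError("prevalence undefined for an empty population")
    idx = [STATUS_INDEX[s] for s in numerator_statuses]
    return float(100.0 * counts[..., idx].sum() / total)


def undiagnosed_share(grid_or_undx, diagnosed: float | None = None) -> float:
    """Percentage of all diabetes cases that are undiagnosed: 100 U/(U+D).

    Accepts either a HealthStateGrid, or two scalars (undiagnosed count,
    diagnosed count) for worked-example arithmetic.
    """
    if isinstance(grid_or_undx, HealthStateGrid):
        totals = grid_or_undx.status_totals()
        u, d = totals["U"], totals["D"]
    else:
        if diagnosed is None:
            raise TypeError("scalar form needs both undiagnosed and diagnosed counts")
        u, d = float(grid_or_undx), float(diagnosed)
    if u + d <= 0:
        raise ValueError("undiagnosed share undefined with no diabetes cases")
    return 100.0 * u / (u + d)


def percent_change(count_from: float, count_to: float) -> float:
    """Signed percent change 100 (to - from)/from."""
    if count_from <= 0:
        raise ValueError("percent change undefined from a nonpositive baseline")
    return 100.0 * (count_to - count_from) / count_from


@dataclass
class ProjectionSummary:
    """Sampled burden trajectories and their quantile summaries.

    dm / undx / pop: arrays (n_samples, n_years, n_sexes, n_groups) of
    diabetes (U+D), undiagnosed (U) and total population counts.
    """

    years: np.ndarray
    age_groups: tuple
    dm: np.ndarray
    undx: np.ndarray
    pop: np.ndarray
    seed: int

    def _cells(self, arr: np.ndarray, credible: float = 0.95) -> pd.DataFrame:
        tail = (1 - credible) / 2
        lo, med, hi = np.quantile(arr, [tail, 0.5, 1 - tail], axis=0)
        rows = []
        for yi, year in enumerate(self.years):
            for si, sex in enumerate(SEXES):
                for gi, group in enumerate(self.age_groups):
                    rows += [
                        (int(year), sex, group, "median", med[yi, si, gi]),
                        (int(year), sex, group, "lower", lo[yi, si, gi]),
                        (int(year), sex, group, "upper", hi[yi, si, gi]),
                    ]
        return pd.DataFrame(rows, columns=["year", "sex", "age_group",
                                           "statistic", "value"])

    def cells(self, credible: float = 0.95) -> pd.DataFrame:
        """Tidy frame of diabetes counts per (year, sex, age group)."""
        return self._cells(self.dm, credible)

    def interval(self, arr_per_sample: np.ndarray,
                 credible: float = 0.95) -> tuple[float, float, float]:
        tail = (1 - credible) / 2
        lo, med, hi = np.quantile(arr_per_sample, [tail, 0.5, 1 - tail])
        return float(med), float(lo), float(hi)

    def _year_index(self, year: float) -> int:
        i = int(np.argmin(np.abs(self.years - year)))
        if abs(self.years[i] - year) > 1e-6:
            raise KeyError(f"year {year} not among projection outputs")
        return i

    def total_dm(self, year: float) -> np.ndarray:
        """Per-sample total diabetes count in a year."""
        return self.dm[:, self._year_index(year)].sum(axis=(1, 2))

    def prevalence_pct(self, year: float) -> np.ndarray:
        yi = self._year_index(year)
        return 100.0 * self.dm[:, yi].sum(axis=(1, 2)) / self.pop[:, yi].sum(axis=(1, 2))

    def undiagnosed_share_pct(self, year: float) -> np.ndarray:
        yi = self._year_index(year)
        dm = self.dm[:, yi].sum(axis=(1, 2))
        return 100.0 * self.undx[:, yi].sum(axis=(1, 2)) / dm

    def percent_change_total(self, year_from: float, year_to: float) -> np.ndarray:
        return 100.0 * (self.total_dm(year_to) - self.total_dm(year_from)) \
            / self.total_dm(year_from)


def project_burden(
    chains: PosteriorChains,
    initial: HealthStateGrid,
    schedule: DemographicSchedule,
    config: ModelConfig,
    *,
    n_samples: int = 500,
    seed: int = 0,
    horizon: float | None = None,
    output_years=None,
    hold_forward: bool = True,
    integrator: IntegratorOptions | None = None,
) -> ProjectionSummary:
    """Propagate posterior uncertainty to the projection horizon.

    Draws are sampled without replacement from the pooled post-burn-in
    chains (errors if fewer are available than requested).
    """
    horizon = config.projection_horizon if horizon is None else float(horizon)
    if horizon > schedule.end_year + 1e-9:
        if not hold_forward:
            raise ScheduleCoverageError(
                f"horizon {horizon} beyond schedule coverage {schedule.end_year} "
                "and hold_forward disabled")
        schedule = schedule.hold_forward(horizon)
    if output_years is None:
        output_years = [2005, 2010, float(config.fit_end), horizon]
    output_years = np.asarray(sorted(set(float(y) for y in output_years)))

    pooled = chains.pooled()
    rng = np.random.default_rng(seed)
    if n_samples > len(pooled):
        raise ValueError(f"requested {n_samples} samples from a pool of {len(pooled)}")
    idx = rng.choice(len(pooled), size=n_samples, replace=False)

    groups = config.incidence_groups
    labels = config.incidence_labels
    dm = np.empty((n_samples, len(output_years), len(SEXES), len(groups)))
    undx = np.empty_like(dm)
    pop = np.empty_like(dm)
    for k, draw in enumerate(pooled[idx]):
        params = chains.parameter_set(draw)
        sim = simulate_disease(initial, params, schedule, config, output_years,
                               integrator=integrator)
        for yi, year in enumerate(output_years):
            counts = sim.at(year).counts
            for gi, (lo, hi) in enumerate(groups):
                block = counts[lo:hi + 1]
                dm[k, yi, :, gi] = block[:, :, 1:].sum(axis=(0, 2))
                undx[k, yi, :, gi] = block[:, :, 1].sum(axis=0)
                pop[k, yi, :, gi] = block.sum(axis=(0, 2))
    return ProjectionSummary(years=output_years, age_groups=labels,
                             dm=dm, undx=undx, pop=pop, seed=seed)


def table1_layout(summary: ProjectionSummary, years=None,
                  age_groups=None) -> tuple[pd.DataFrame, str]:
    """Printed-table layout: counts in thousands, cells rounded to the
    nearest 10 thousand, row totals computed as the sum of the rounded
    cells so the printed identity holds exactly.
    """
    years = [int(y) for y in (years if years is not None else summary.years)]
    age_groups = tuple(age_groups if age_groups is not None else summary.age_groups)
    med = np.quantile(summary.dm, 0.5, axis=0)  # (n_years, 2, n_groups)
    rows = []
    for year in years:
        yi = summary._year_index(year)
        cells = []
        for gi, group in enumerate(age_groups):
            g_all = list(summary.age_groups)
            if group not in g_all:
                raise KeyError(f"age group {group!r} not in projection")
            gj = g_all.index(group)
            for si in (1, 0):  # male column first, as printed
                cells.append(round(med[yi, si, gj] / 10000.0) * 10)
        rows.append([year] + cells + [int(sum(cells))])
    cols = ["year"]
    for group in age_groups:
        cols += [f"{group}_male", f"{group}_female"]
    cols.append("total")
    frame = pd.DataFrame(rows, columns=cols)
    lines = ["Projection (thousands) of people with diabetes by age group",
             "\t".join(cols)]
    for row in rows:
        lines.append("\t".join(str(v) for v in row))
    return frame, "\n".join(lines)
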