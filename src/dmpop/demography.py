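"""Continuous-time cohort ODE model of a population's size and age/sex structure.

The population is divided into 101 annual age classes per sex.  Aging is a
linear chain at rate 1/year between adjacent classes; the outflow of the
oldest class (100) is routed to death.  Births enter age class 0, produced
by women aged 15-50 at age-specific fertility rates and split by the sex
ratio at birth.  A crude net migration rate (per 1000 population per year)
is shared proportionally across every age/sex compartment.  Fertility and
mortality schedules are piecewise-constant in calendar time (decade
resolution by default); integration is split at schedule breakpoints so the
right-hand side is smooth within each segment.

Auxiliary integrals accumulate cumulative births, deaths and net migrants,
so every simulation carries its own conservation audit:
``dN_total/dt = births - deaths + migration`` exactly.
"""

from __future__ import annotations


from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .grids import N_AGES, SEXES, AgeSexGrid

FERTILE_MIN, FERTILE_MAX = 15, 50

_RATE_TYPES = ("fertility", "mortality", "net_migration", "sex_ratio_at_birth")


class ScheduleCoverageError(ValueError):
    """Requested time lies outside the schedule's calendar coverage."""


@dataclass
class IntegratorOptions:
    """Settings for the ODE solver.

    LSODA (stiff-capable through automatic method switching) is the default
    for standalone runs.  The calibration loop uses ``method="rk4"``, a
    compiled fixed-step integrator for the disease system, because the
    system is non-stiff and adaptive-solver overhead dominates at this size.
    """

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    # negatives larger than -clip_rtol * max(1, total) are clipped at output
    clip_rtol: float = 1e-7
    # fixed step size (years) for the compiled "rk4" method (disease model only)
    step: float = 0.1


FAST_INTEGRATOR = IntegratorOptions(method="rk4", rtol=1e-6, atol=1e-8)


def _interval_index(edges: np.ndarray, t: float, what: str) -> int:
    """Index of the piecewise-constant interval containing t.

    Intervals are right-open [e_i, e_{i+1}); the final edge is inclusive.
    """
    t = float(t)
    eps = 1e-9
    if t < edges[0] - eps or t > edges[-1] + eps:
        raise ScheduleCoverageError(
            f"{what}: time {t} outside schedule coverage [{edges[0]}, {edges[-1]}]"
        )
    return int(np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(edges) - 2))


@dataclass
class DemographicSchedule:
    """Piecewise-constant fertility/mortality schedules plus a migration series.

    Parameters
    ----------
    edges:
        Interval edges (K+1 calendar years) for fertility and mortality.
    fertility:
        (K, 101) births per woman-year by maternal age class; zero outside
        ages 15-50.
    mortality:
        (K, 101, 2) deaths per person-year by age class and sex.
    migration_edges, migration:
        Piecewise-constant crude net migration, (M+1,) edges and (M,) values
        in net migrants per 1000 population per year (may be negative).
    sex_ratio_at_birth:
        Proportion of births that are male (default 0.512).
    """

    edges: np.ndarray
    fertility: np.ndarray
    mortality: np.ndarray
    migration_edges: np.ndarray
    migration: np.ndarray
    sex_ratio_at_birth: float = 0.512

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.fertility = np.asarray(self.fertility, dtype=float)
        self.mortality = np.asarray(self.mortality, dtype=float)
        self.migration_edges = np.asarray(self.migration_edges, dtype=float)
        self.migration = np.asarray(self.migration, dtype=float)
        k = len(self.edges) - 1
        if k < 1 or np.any(np.diff(self.edges) <= 0):
            raise ValueError("schedule edges must be strictly increasing, >= 2 values")
        if self.fertility.shape != (k, N_AGES):
            raise ValueError(f"fertility must have shape ({k}, {N_AGES})")
        if self.mortality.shape != (k, N_AGES, 2):
            raise ValueError(f"mortality must have shape ({k}, {N_AGES}, 2)")
        if self.migration.shape != (len(self.migration_edges) - 1,):
            raise ValueError("migration values must match migration edges")
        ages = np.arange(N_AGES)
        outside = (ages < FERTILE_MIN) | (ages > FERTILE_MAX)
        if np.any(self.fertility[:, outside] != 0):
            raise ValueError("fertility must be zero outside ages 15-50")
        if self.fertility.min() < 0 or self.mortality.min() < 0:
            raise ValueError("fertility and mortality must be nonnegative")
        if not 0 < self.sex_ratio_at_birth < 1:
            raise ValueError("sex ratio at birth must lie in (0, 1)")

    @property
    def start_year(self) -> float:
        return float(min(self.edges[0], self.migration_edges[0]))

    @property
    def end_year(self) -> float:
        return float(max(self.edges[-1], self.migration_edges[-1]))

    def fertility_at(self, t: float) -> np.ndarray:
        return self.fertility[_interval_index(self.edges, t, "fertility")]

    def mortality_at(self, t: float) -> np.ndarray:
        return self.mortality[_interval_index(self.edges, t, "mortality")]

    def migration_at(self, t: float) -> float:
        return float(self.migration[_interval_index(self.migration_edges, t, "migration")])

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        """All schedule discontinuities strictly inside (t0, t1)."""
        pts = np.concatenate([self.edges, self.migration_edges])
        pts = pts[(pts > t0 + 1e-12) & (pts < t1 - 1e-12)]
        return np.unique(pts)

    def hold_forward(self, end_year: float) -> "DemographicSchedule":
        """Extend coverage to end_year, repeating the last interval's rates."""
        if end_year <= self.end_year:
            return self
        edges = np.append(self.edges, max(end_year, self.edges[-1] + 1e-6))
        fert = np.vstack([self.fertility, self.fertility[-1:]])
        mort = np.concatenate([self.mortality, self.mortality[-1:]], axis=0)
        m_edges = np.append(self.migration_edges, max(end_year, self.migration_edges[-1] + 1e-6))
        mig = np.append(self.migration, self.migration[-1])
        return replace(self, edges=edges, fertility=fert, mortality=mort,
                       migration_edges=m_edges, migration=mig)

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(len(self.edges) - 1):
            y0, y1 = self.edges[k], self.edges[k + 1]
            for a in range(FERTILE_MIN, FERTILE_MAX + 1):
                rows.append((y0, y1, "female", a, "fertility", self.fertility[k, a]))
            for si, sex in enumerate(SEXES):
                for a in range(N_AGES):
                    rows.append((y0, y1, sex, a, "mortality", self.mortality[k, a, si]))
        for m in range(len(self.migration)):
            rows.append((self.migration_edges[m], self.migration_edges[m + 1],
                         "all", -1, "net_migration", self.migration[m]))
        rows.append((self.edges[0], self.edges[-1], "all", -1,
                     "sex_ratio_at_birth", self.sex_ratio_at_birth))
        return pd.DataFrame(
            rows, columns=["year_start", "year_end", "sex", "age", "rate_type", "value"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DemographicSchedule":
        required = ["year_start", "year_end", "sex", "age", "rate_type", "value"]
        if list(frame.columns) != required:
            raise ValueError(f"schedule table must have columns {required}, "
                             f"got {list(frame.columns)}")
        bad = set(frame["rate_type"]) - set(_RATE_TYPES)
        if bad:
            raise ValueError(f"unknown rate_type values: {sorted(bad)}")

        mort = frame[frame["rate_type"] == "mortality"]
        fert = frame[frame["rate_type"] == "fertility"]
        mig = frame[frame["rate_type"] == "net_migration"].sort_values("year_start")
        srb_rows = frame[frame["rate_type"] == "sex_ratio_at_birth"]

        edges = np.unique(np.concatenate([mort["year_start"].to_numpy(float),
                                          mort["year_end"].to_numpy(float)]))
        k = len(edges) - 1
        mortality = np.full((k, N_AGES, 2), np.nan)
        for _, row in mort.iterrows():
            ki = _interval_index(edges, (row["year_start"] + row["year_end"]) / 2, "mortality")
            age = int(row["age"])
            if not 0 <= age < N_AGES:
                raise ValueError(f"mortality age {age} outside 0..100")
            mortality[ki, age, {"female": 0, "male": 1}[row["sex"]]] = row["value"]
        if np.isnan(mortality).any():
            ki, a, si = np.argwhere(np.isnan(mortality))[0]
            raise ValueError(
                f"missing mortality for interval [{edges[ki]}, {edges[ki + 1]}], "
                f"age {a}, sex {SEXES[si]}"
            )
        fertility = np.zeros((k, N_AGES))
        seen = np.zeros((k, N_AGES), dtype=bool)
        for _, row in fert.iterrows():
            if row["sex"] != "female":
                raise ValueError("fertility rows must have sex='female'")
            age = int(row["age"])
            if not FERTILE_MIN <= age <= FERTILE_MAX:
                if row["value"] != 0:
                    raise ValueError(f"nonzero fertility at age {age} outside 15-50")
                continue
            ki = _interval_index(edges, (row["year_start"] + row["year_end"]) / 2, "fertility")
            fertility[ki, age] = row["value"]
            seen[ki, age] = True
        if not seen[:, FERTILE_MIN:FERTILE_MAX + 1].all():
            ki, a = np.argwhere(~seen[:, FERTILE_MIN:FERTILE_MAX + 1])[0]
            raise ValueError(
                f"missing fertility for interval [{edges[ki]}, {edges[ki + 1]}], "
                f"age {a + FERTILE_MIN}"
            )
        if mig.empty:
            raise ValueError("schedule table has no net_migration rows")
        migration_edges = np.append(mig["year_start"].to_numpy(float),
                                    mig["year_end"].to_numpy(float)[-1])
        migration = mig["value"].to_numpy(float)
        srb = 0.512 if srb_rows.empty else float(srb_rows["value"].iloc[0])
        return cls(edges=edges, fertility=fertility, mortality=mortality,
                   migration_edges=migration_edges, migration=migration,
                   sex_ratio_at_birth=srb)

    @classmethod
    def from_csv(cls, path) -> "DemographicSchedule":
        return cls.from_frame(pd.read_csv(path))


# ----------------------------------------------------------------- dynamics

def demographic_derivative(
    state: AgeSexGrid,
    schedule: DemographicSchedule,
    t: float,
    *,
    aging: bool = True,
) -> np.ndarray:
    """Instantaneous rate of change of the (101, 2) count grid at time t.

    Flows: aging chain at 1/yr (age-100 outflow is a death), age/sex
    mortality, proportional net migration, and births into age class 0
    split by the sex ratio at birth.
    """
    counts = state.counts
    mu = schedule.mortality_at(t)
    mig = schedule.migration_at(t) / 1000.0
    d = (mig - mu) * counts
    if aging:
        d -= counts
        d[1:] += counts[:-1]
    fert = schedule.fertility_at(t)
    births = float(fert @ counts[:, 0])
    d[0, 0] += (1.0 - schedule.sex_ratio_at_birth) * births
    d[0, 1] += schedule.sex_ratio_at_birth * births
    return d


@dataclass
class DemographySimResult:
    """Trajectory plus cumulative birth/death/migration flow integrals."""

    grids: list[AgeSexGrid]
    times: np.ndarray
    cumulative_flows: pd.DataFrame  # columns births, deaths, migration (cumulative)

    def at(self, year: float) -> AgeSexGrid:
        i = int(np.argmin(np.abs(self.times - year)))
        if abs(self.times[i] - year) > 1e-6:
            raise KeyError(f"year {year} not among output times")
        return self.grids[i]

    def conservation_residual(self) -> float:
        """|dN_total - (births - deaths + migration)| / N_total, worst output."""
        worst = 0.0
        n0 = self.grids[0].total
        f = self.cumulative_flows
        for i, g in enumerate(self.grids):
            expected = n0 + f["births"].iloc[i] - f["deaths"].iloc[i] + f["migration"].iloc[i]
            worst = max(worst, abs(g.total - expected) / max(g.total, 1.0))
        return worst


class IntegrationError(RuntimeError):
    pass


def _integrate_segments(rhs_factory, y0, t0, t1, interior_breaks, t_eval, options):
    """Piecewise solve_ivp across schedule breakpoints; returns states at t_eval.

    rhs_factory(t_mid) binds the piecewise-constant rates for one segment,
    so the returned right-hand side does no schedule lookups per call.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    seg_edges = np.unique(np.concatenate([[t0, t1], interior_breaks]))
    out = np.empty((len(t_eval), len(y0)))
    filled = np.zeros(len(t_eval), dtype=bool)
    y = np.asarray(y0, dtype=float)
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        inside = (t_eval >= a - 1e-12) & (t_eval <= b + 1e-12) & ~filled
        pts = np.clip(t_eval[inside], a, b)
        sol = solve_ivp(rhs_factory((a + b) / 2.0), (a, b), y,
                        method=options.method, rtol=options.rtol,
                        atol=options.atol, t_eval=np.unique(np.concatenate([pts, [b]])),
                        dense_output=False)
        if not sol.success:
            raise IntegrationError(f"integration failed in [{a}, {b}]: {sol.message}")
        if inside.any():
            # map each requested point to its column in sol.y
            cols = np.searchsorted(sol.t, np.clip(t_eval[inside], a, b))
            out[inside] = sol.y[:, np.clip(cols, 0, len(sol.t) - 1)].T
            filled[inside] = True
        y = sol.y[:, -1]
    if not filled.all():
        raise IntegrationError("internal error: some output times not covered")
    return out


def _clip_counts(counts: np.ndarray, options: IntegratorOptions, what: str) -> np.ndarray:
    tol = options.clip_rtol * max(1.0, counts.sum())
    if counts.min() < -tol:
        raise IntegrationError(
            f"{what}: negative count {counts.min():g} beyond clip tolerance {tol:g}"
        )
    return np.clip(counts, 0.0, None)


def simulate_population(
    initial: AgeSexGrid,
    schedule: DemographicSchedule,
    t_span: tuple[float, float],
    output_years,
    *,
    aging: bool = True,
    integrator: IntegratorOptions | None = None,
) -> DemographySimResult:
    """Integrate the demographic ODE over t_span, reporting at output_years."""
    options = integrator or IntegratorOptions()
    t0, t1 = float(t_span[0]), float(t_span[1])
    if abs(initial.reference_time - t0) > 1e-9:
        raise ValueError("initial.reference_time must equal the start of t_span")
    output_years = np.asarray(sorted(set(float(y) for y in output_years)))
    if output_years.min() < t0 - 1e-9 or output_years.max() > t1 + 1e-9:
        raise ValueError("output_years must lie within t_span")
    if t0 < schedule.start_year - 1e-9 or t1 > schedule.end_year + 1e-9:
        raise ScheduleCoverageError(
            f"t_span {t_span} outside schedule coverage "
            f"[{schedule.start_year}, {schedule.end_year}]"
        )

    n = N_AGES * 2
    srb = schedule.sex_ratio_at_birth

    def rhs_factory(t_mid):
        mu = schedule.mortality_at(t_mid)
        mig = schedule.migration_at(t_mid) / 1000.0
        fert = schedule.fertility_at(t_mid)

        def rhs(t, y):
            counts = y[:n].reshape(N_AGES, 2)
            d = (mig - mu) * counts
            deaths = float((mu * counts).sum())
            if aging:
                d -= counts
                d[1:] += counts[:-1]
                deaths += float(counts[-1].sum())  # age-100 outflow dies
            births = float(fert @ counts[:, 0])
            d[0, 0] += (1.0 - srb) * births
            d[0, 1] += srb * births
            mig_flow = mig * float(counts.sum())
            return np.concatenate([d.ravel(), [births, deaths, mig_flow]])

        return rhs

    y0 = np.concatenate([initial.counts.ravel(), [0.0, 0.0, 0.0]])
    states = _integrate_segments(rhs_factory, y0, t0, t1,
                                 schedule.breakpoints(t0, t1),
                                 output_years, options)
    grids, flows = [], []
    for t, y in zip(output_years, states):
        counts = _clip_counts(y[:n].reshape(N_AGES, 2), options, f"t={t}")
        grids.append(AgeSexGrid(counts=counts, reference_time=t))
        flows.append(y[n:])
    flow_frame = pd.DataFrame(flows, columns=["births", "deaths", "migration"])
    flow_frame.insert(0, "year", output_years)
    return DemographySimResult(grids=grids, times=output_years,
                               cumulative_flows=flow_frame)
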