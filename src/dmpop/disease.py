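"""Three-status diabetes dynamics overlaid on the demographic cohort model.

Each age/sex cell is split into healthy (H), undiagnosed diabetes (U) and
diagnosed diabetes (D).  Progression is irreversible: H -> U at an
age-group/sex-specific incidence rate (constant in calendar time), U -> D at
a positive-screening rate specific to screening age group, sex and calendar
period, and both diabetic statuses carry an excess case-fatality hazard on
top of background mortality.  Births enter H only; no one below the
screening policy floor (age 15 by default) can be diagnosed.

The joint system also integrates auxiliary flow accumulators (true new
diagnoses, onsets, deaths by status, births, net migrants) per incidence
age group and sex, from which an annual flow ledger is assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .demography import (
    DemographicSchedule,
    IntegrationError,
    IntegratorOptions,
    ScheduleCoverageError,
    _clip_counts,
    _integrate_segments,
)
from .grids import N_AGES, SEXES, STATUSES, AgeSexGrid, HealthStateGrid

# calibrated quantities per block
INCIDENCE_GROUPS = ((0, 39), (40, 49), (50, 59), (60, 100))
SCREENING_GROUPS = ((15, 34), (35, 59), (60, 100))
PERIOD_LABELS = ("2005-2009", "2010-2015")
REPORTING_LABELS = ("pre-2005", "2005-2009", "2010-2015")

DIAGNOSED_CASE_FATALITY = 18.4 / 1000.0  # per diagnosed person-year


def _group_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}" if hi < 100 else f"{lo}+"


@dataclass
class ModelConfig:
    """Structural configuration: calendar anchors and age-group tables."""

    disease_introduction_year: float = 2000.0
    fit_start: float = 2005.0
    fit_end: float = 2015.0
    projection_horizon: float = 2035.0
    incidence_groups: tuple = INCIDENCE_GROUPS
    screening_groups: tuple = SCREENING_GROUPS
    screening_floor: int = 15
    period_boundary: float = 2010.0  # start of the second screening period

    def __post_init__(self) -> None:
        if not (self.disease_introduction_year <= self.fit_start
                <= self.fit_end <= self.projection_horizon):
            raise ValueError("require introduction <= fit start <= fit end <= horizon")
        for groups, what in ((self.incidence_groups, "incidence"),
                             (self.screening_groups, "screening")):
            covered = np.zeros(N_AGES, dtype=bool)
            for lo, hi in groups:
                if not (0 <= lo <= hi <= 100):
                    raise ValueError(f"{what} group ({lo}, {hi}) outside 0..100")
                covered[lo:hi + 1] = True
        if not covered[self.screening_floor:].all():
            raise ValueError("screening groups must cover every age >= screening floor")

    @property
    def incidence_labels(self) -> tuple:
        return tuple(_group_label(lo, hi) for lo, hi in self.incidence_groups)

    @property
    def screening_labels(self) -> tuple:
        return tuple(_group_label(lo, hi) for lo, hi in self.screening_groups)

    def incidence_group_of_age(self) -> np.ndarray:
        """(101,) index into incidence_groups for each age class."""
        idx = np.full(N_AGES, -1, dtype=int)
        for g, (lo, hi) in enumerate(self.incidence_groups):
            idx[lo:hi + 1] = g
        if (idx < 0).any():
            raise ValueError("incidence groups must cover ages 0..100")
        return idx

    def screening_group_of_age(self) -> np.ndarray:
        """(101,) index into screening_groups; -1 below the screening floor."""
        idx = np.full(N_AGES, -1, dtype=int)
        for k, (lo, hi) in enumerate(self.screening_groups):
            idx[max(lo, self.screening_floor):hi + 1] = k
        return idx

    def period_index(self, t: float) -> int:
        """Screening period: the first period applies before 2005 too, the
        second persists beyond the fit window (rates constant over time)."""
        return 0 if t < self.period_boundary else 1

    def reporting_index(self, t: float) -> int:
        if t < self.fit_start:
            return 0
        return 1 if t < self.period_boundary else 2


@dataclass
class ParameterSet:
    """The 32 model quantities: 31 calibrated + 1 fixed.

    incidence: (4, 2) onsets per healthy person-year, [incidence group, sex].
    screening: (3, 2, 2) positive screens per undiagnosed person-year,
        [screening group, sex, period].
    excess_mortality_undx: (4, 2) excess deaths per undiagnosed person-year.
    reporting: (3,) proportion of true new diagnoses captured by surveillance,
        [pre-2005, 2005-2009, 2010-2015].
    cfr_diagnosed: excess deaths per diagnosed person-year (fixed, not
        calibrated; default 18.4/1000).
    """

    incidence: np.ndarray
    screening: np.ndarray
    excess_mortality_undx: np.ndarray
    reporting: np.ndarray
    cfr_diagnosed: float = DIAGNOSED_CASE_FATALITY

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=float)
        self.screening = np.asarray(self.screening, dtype=float)
        self.excess_mortality_undx = np.asarray(self.excess_mortality_undx, dtype=float)
        self.reporting = np.asarray(self.reporting, dtype=float)
        if self.incidence.shape != (4, 2):
            raise ValueError("incidence must have shape (4, 2)")
        if self.screening.shape != (3, 2, 2):
            raise ValueError("screening must have shape (3, 2, 2)")
        if self.excess_mortality_undx.shape != (4, 2):
            raise ValueError("excess_mortality_undx must have shape (4, 2)")
        if self.reporting.shape != (3,):
            raise ValueError("reporting must have shape (3,)")
        for arr, what in ((self.incidence, "incidence"), (self.screening, "screening"),
                          (self.excess_mortality_undx, "excess_mortality_undx")):
            if arr.min() < 0:
                raise ValueError(f"{what} rates must be nonnegative")
        if self.reporting.min() < 0 or self.reporting.max() > 1:
            raise ValueError("reporting proportions must lie in [0, 1]")
        if self.cfr_diagnosed < 0:
            raise ValueError("cfr_diagnosed must be nonnegative")

    # canonical flat ordering of the 31 calibrated values -------------------

    @staticmethod
    def calibrated_names(config: ModelConfig | None = None) -> list[str]:
        config = config or ModelConfig()
        names = []
        for g in config.incidence_labels:
            for s in SEXES:
                names.append(f"incidence[{g},{s}]")
        for k in config.screening_labels:
            for s in SEXES:
                for p in PERIOD_LABELS:
                    names.append(f"screening[{k},{s},{p}]")
        for g in config.incidence_labels:
            for s in SEXES:
                names.append(f"cfr_undiagnosed[{g},{s}]")
        for p in REPORTING_LABELS:
            names.append(f"reporting[{p}]")
        return names

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.incidence.ravel(), self.screening.ravel(),
                               self.excess_mortality_undx.ravel(), self.reporting])

    @classmethod
    def from_vector(cls, vec: np.ndarray,
                    cfr_diagnosed: float = DIAGNOSED_CASE_FATALITY) -> "ParameterSet":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (31,):
            raise ValueError("parameter vector must have 31 entries")
        return cls(incidence=vec[:8].reshape(4, 2),
                   screening=vec[8:20].reshape(3, 2, 2),
                   excess_mortality_undx=vec[20:28].reshape(4, 2),
                   reporting=vec[28:31],
                   cfr_diagnosed=cfr_diagnosed)

    def simulation_key(self) -> bytes:
        """Hashable key over the quantities that affect the ODE trajectory
        (reporting only rescales observations, so it is excluded)."""
        return (self.incidence.tobytes() + self.screening.tobytes()
                + self.excess_mortality_undx.tobytes()
                + np.float64(self.cfr_diagnosed).tobytes())

    def to_frame(self, config: ModelConfig | None = None) -> pd.DataFrame:
        config = config or ModelConfig()
        rows = []
        for gi, g in enumerate(config.incidence_labels):
            for si, s in enumerate(SEXES):
                rows.append(("incidence", g, s, "", self.incidence[gi, si]))
        for ki, k in enumerate(config.screening_labels):
            for si, s in enumerate(SEXES):
                for pi, p in enumerate(PERIOD_LABELS):
                    rows.append(("screening", k, s, p, self.screening[ki, si, pi]))
        for gi, g in enumerate(config.incidence_labels):
            for si, s in enumerate(SEXES):
                rows.append(("cfr_undiagnosed", g, s, "", self.excess_mortality_undx[gi, si]))
        for pi, p in enumerate(REPORTING_LABELS):
            rows.append(("reporting", "", "", p, self.reporting[pi]))
        rows.append(("cfr_diagnosed", "", "", "", self.cfr_diagnosed))
        return pd.DataFrame(rows, columns=["name", "group", "sex", "period", "value"])

    def to_csv(self, path, config: ModelConfig | None = None) -> None:
        self.to_frame(config).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   config: ModelConfig | None = None) -> "ParameterSet":
        config = config or ModelConfig()
        frame = frame.fillna("")
        def grab(name, **keys):
            m = frame["name"] == name
            for col, val in keys.items():
                m &= frame[col].astype(str) == str(val)
            sub = frame[m]
            if len(sub) != 1:
                raise ValueError(f"expected exactly one row for {name} {keys}, got {len(sub)}")
            return float(sub["value"].iloc[0])
        inc = np.array([[grab("incidence", group=g, sex=s) for s in SEXES]
                        for g in config.incidence_labels])
        scr = np.array([[[grab("screening", group=k, sex=s, period=p)
                          for p in PERIOD_LABELS] for s in SEXES]
                        for k in config.screening_labels])
        exm = np.array([[grab("cfr_undiagnosed", group=g, sex=s) for s in SEXES]
                        for g in config.incidence_labels])
        rep = np.array([grab("reporting", period=p) for p in REPORTING_LABELS])
        cfr = grab("cfr_diagnosed")
        return cls(incidence=inc, screening=scr, excess_mortality_undx=exm,
                   reporting=rep, cfr_diagnosed=cfr)

    @classmethod
    def from_csv(cls, path, config: ModelConfig | None = None) -> "ParameterSet":
        return cls.from_frame(pd.read_csv(path), config)

    # age-class expansions ---------------------------------------------------

    def incidence_by_age(self, config: ModelConfig) -> np.ndarray:
        """(101, 2) onset rate per age class and sex."""
        return self.incidence[config.incidence_group_of_age()]

    def screening_by_age(self, config: ModelConfig, t: float) -> np.ndarray:
        """(101, 2) positive-screening rate at time t; zero below the floor."""
        k_of_age = config.screening_group_of_age()
        sig = np.zeros((N_AGES, 2))
        ok = k_of_age >= 0
        sig[ok] = self.screening[k_of_age[ok], :, config.period_index(t)]
        return sig

    def excess_mortality_by_age(self, config: ModelConfig) -> np.ndarray:
        return self.excess_mortality_undx[config.incidence_group_of_age()]

    def reporting_at(self, config: ModelConfig, t: float) -> float:
        return float(self.reporting[config.reporting_index(t)])


def mean_time_to_diagnosis(params: ParameterSet, group: int, sex: int,
                           period: int) -> float:
    """Expected sojourn in the undiagnosed state before a positive screen,
    ignoring competing mortality: 1/sigma (years)."""
    sigma = params.screening[group, sex, period]
    if sigma <= 0:
        return np.inf
    return 1.0 / sigma


# ------------------------------------------------------------------ dynamics

def disease_derivative(
    state: HealthStateGrid,
    params: ParameterSet,
    schedule: DemographicSchedule,
    config: ModelConfig,
    t: float,
    *,
    aging: bool = True,
) -> np.ndarray:
    """Rate of change of the (101, 2, 3) health-state grid at time t."""
    counts = state.counts
    mu = schedule.mortality_at(t)[:, :, None]
    mig = schedule.migration_at(t) / 1000.0
    d = (mig - mu) * counts
    if aging:
        d -= counts
        d[1:] += counts[:-1]
    births = float(schedule.fertility_at(t) @ counts[:, 0, :].sum(axis=1))
    srb = schedule.sex_ratio_at_birth
    d[0, 0, 0] += (1.0 - srb) * births  # births enter H only
    d[0, 1, 0] += srb * births
    lam = params.incidence_by_age(config)
    sig = params.screening_by_age(config, t)
    du = params.excess_mortality_by_age(config)
    onset = lam * counts[:, :, 0]
    diagnosed = sig * counts[:, :, 1]
    d[:, :, 0] -= onset
    d[:, :, 1] += onset - diagnosed - du * counts[:, :, 1]
    d[:, :, 2] += diagnosed - params.cfr_diagnosed * counts[:, :, 2]
    return d


@dataclass
class DiseaseSimResult:
    """Health-state trajectory plus an annual flow ledger.

    ledger columns: year, sex, age_group, onsets, true_diagnoses, deaths_H,
    deaths_U, deaths_D — each the integral of the corresponding flow over
    [year, year+1).
    """

    grids: list[HealthStateGrid]
    times: np.ndarray
    ledger: pd.DataFrame
    cumulative_flows: pd.DataFrame  # births, deaths, migration per output time
    config: ModelConfig
    # annual flow arrays behind the ledger frame, for vectorized consumers:
    # (n_years, n_groups, n_sexes[, n_statuses]), year order = ledger_years
    ledger_years: np.ndarray | None = None
    diagnoses_annual: np.ndarray | None = None
    onsets_annual: np.ndarray | None = None
    deaths_annual: np.ndarray | None = None

    def at(self, year: float) -> HealthStateGrid:
        i = int(np.argmin(np.abs(self.times - year)))
        if abs(self.times[i] - year) > 1e-6:
            raise KeyError(f"year {year} not among output times")
        return self.grids[i]

    def conservation_residual(self) -> float:
        worst = 0.0
        n0 = self.grids[0].total
        f = self.cumulative_flows
        for i, g in enumerate(self.grids):
            expected = n0 + f["births"].iloc[i] - f["deaths"].iloc[i] + f["migration"].iloc[i]
            worst = max(worst, abs(g.total - expected) / max(g.total, 1.0))
        return worst


def simulate_disease(
    initial: HealthStateGrid,
    params: ParameterSet,
    schedule: DemographicSchedule,
    config: ModelConfig,
    output_years,
    *,
    aging: bool = True,
    integrator: IntegratorOptions | None = None,
) -> DiseaseSimResult:
    """Integrate the joint demographic + disease system.

    The ledger is assembled from year-boundary accumulator differences, so
    integer year boundaries spanning the run are always added to the output
    grid internally.
    """
    options = integrator or IntegratorOptions()
    t0 = float(initial.reference_time)
    output_years = sorted(set(float(y) for y in output_years))
    t1 = max(output_years)
    if min(output_years) < t0 - 1e-9:
        raise ValueError("output_years must not precede the initial time")
    if t0 < schedule.start_year - 1e-9 or t1 > schedule.end_year + 1e-9:
        raise ScheduleCoverageError(
            f"[{t0}, {t1}] outside schedule coverage "
            f"[{schedule.start_year}, {schedule.end_year}]"
        )

    year_marks = np.arange(np.ceil(t0 - 1e-9), np.floor(t1 + 1e-9) + 1)
    eval_times = np.unique(np.concatenate([output_years, year_marks, [t0, t1]]))

    n = N_AGES * 2 * 3
    g_of_age = config.incidence_group_of_age()
    n_groups = len(config.incidence_groups)
    G = np.zeros((n_groups, N_AGES))
    G[g_of_age, np.arange(N_AGES)] = 1.0
    srb = schedule.sex_ratio_at_birth
    lam = params.incidence_by_age(config)
    du = params.excess_mortality_by_age(config)
    cfr_d = params.cfr_diagnosed

    # period boundaries are discontinuities of sigma
    breaks = np.unique(np.concatenate([
        schedule.breakpoints(t0, t1),
        [b for b in (config.period_boundary, config.fit_start) if t0 < b < t1],
    ])) if t1 > t0 else np.array([])

    # accumulator layout after the state block:
    #   onsets (4, 2), true diagnoses (4, 2), deaths (4, 2, 3), births, migration
    n_acc = n_groups * 2 * 2 + n_groups * 2 * 3 + 2

    def rhs_factory(t_mid):
        mu3 = schedule.mortality_at(t_mid)[:, :, None]
        mig = schedule.migration_at(t_mid) / 1000.0
        fert = schedule.fertility_at(t_mid)
        sig = params.screening_by_age(config, t_mid)

        def rhs(t, y):
            counts = y[:n].reshape(N_AGES, 2, 3)
            d = (mig - mu3) * counts
            deaths = mu3 * counts
            if aging:
                d -= counts
                d[1:] += counts[:-1]
                deaths[-1] += counts[-1]  # age-100 outflow dies
            births = float(fert @ counts[:, 0, :].sum(axis=1))
            d[0, 0, 0] += (1.0 - srb) * births
            d[0, 1, 0] += srb * births
            onset = lam * counts[:, :, 0]
            diagnosed = sig * counts[:, :, 1]
            excess_u = du * counts[:, :, 1]
            excess_d = cfr_d * counts[:, :, 2]
            d[:, :, 0] -= onset
            d[:, :, 1] += onset - diagnosed - excess_u
            d[:, :, 2] += diagnosed - excess_d
            deaths[:, :, 1] += excess_u
            deaths[:, :, 2] += excess_d
            onset_g = G @ onset
            diag_g = G @ diagnosed
            deaths_g = G @ deaths.reshape(N_AGES, 6)
            mig_flow = mig * float(counts.sum())
            return np.concatenate([d.ravel(), onset_g.ravel(), diag_g.ravel(),
                                   deaths_g.ravel(), [births, mig_flow]])

        return rhs

    y0 = np.concatenate([initial.counts.ravel(), np.zeros(n_acc)])
    if options.method == "rk4":
        states = _rk4_states(y0, t0, t1, breaks, eval_times, params, schedule,
                             config, aging, options.step)
    else:
        states = _integrate_segments(rhs_factory, y0, t0, t1, breaks,
                                     eval_times, options)

    grids, flows, acc_by_year = [], [], {}
    out_set = set(np.round(np.asarray(output_years), 9))
    for t, y in zip(eval_times, states):
        acc = y[n:]
        onsets = acc[:8].reshape(n_groups, 2)
        diags = acc[8:16].reshape(n_groups, 2)
        deaths = acc[16:16 + n_groups * 6].reshape(n_groups, 2, 3)
        births, mig_flow = acc[-2], acc[-1]
        if abs(t - round(t)) < 1e-9:
            acc_by_year[int(round(t))] = (onsets, diags, deaths)
        if round(t, 9) in out_set:
            counts = _clip_counts(y[:n].reshape(N_AGES, 2, 3), options, f"t={t}")
            grids.append(HealthStateGrid(counts=counts, reference_time=t))
            flows.append((t, births, deaths.sum(), mig_flow))

    years = sorted(acc_by_year)
    led_years = np.array([ya for ya, yb in zip(years[:-1], years[1:])
                          if yb == ya + 1], dtype=int)
    onsets_annual = np.empty((len(led_years), n_groups, 2))
    diagnoses_annual = np.empty_like(onsets_annual)
    deaths_annual = np.empty((len(led_years), n_groups, 2, 3))
    for i, ya in enumerate(led_years):
        o0, d0, m0 = acc_by_year[ya]
        o1, d1, m1 = acc_by_year[ya + 1]
        onsets_annual[i] = o1 - o0
        diagnoses_annual[i] = d1 - d0
        deaths_annual[i] = m1 - m0

    ny, ns = len(led_years), len(SEXES)
    ledger = pd.DataFrame({
        "year": np.repeat(led_years, n_groups * ns),
        "sex": np.tile(np.repeat(SEXES, n_groups), ny),
        "age_group": np.tile(config.incidence_labels, ny * ns),
        "onsets": onsets_annual.transpose(0, 2, 1).ravel(),
        "true_diagnoses": diagnoses_annual.transpose(0, 2, 1).ravel(),
        "deaths_H": deaths_annual[..., 0].transpose(0, 2, 1).ravel(),
        "deaths_U": deaths_annual[..., 1].transpose(0, 2, 1).ravel(),
        "deaths_D": deaths_annual[..., 2].transpose(0, 2, 1).ravel(),
    })
    flow_frame = pd.DataFrame(flows, columns=["year", "births", "deaths", "migration"])
    return DiseaseSimResult(
        grids=grids, times=np.array([g.reference_time for g in grids]),
        ledger=ledger, cumulative_flows=flow_frame[["births", "deaths", "migration"]]
        .assign(year=flow_frame["year"]), config=config,
        ledger_years=led_years, diagnoses_annual=diagnoses_annual,
        onsets_annual=onsets_annual, deaths_annual=deaths_annual)


def _rk4_states(y0, t0, t1, breaks, eval_times, params, schedule, config,
                aging, step):
    """Fixed-step RK4 trajectory via the compiled kernel, one constant-rate
    stretch at a time, reporting the state at every eval time."""
    from ._fastpath import rk4_segment

    knots = np.unique(np.concatenate([eval_times, breaks, [t0, t1]]))
    g_of_age = config.incidence_group_of_age().astype(np.int64)
    lam = np.ascontiguousarray(params.incidence_by_age(config))
    du = np.ascontiguousarray(params.excess_mortality_by_age(config))
    cfr_d = float(params.cfr_diagnosed)
    srb = float(schedule.sex_ratio_at_birth)
    out = np.empty((len(eval_times), len(y0)))
    filled = np.zeros(len(eval_times), dtype=bool)
    hit = np.abs(eval_times - t0) < 1e-9
    out[hit] = y0
    filled |= hit
    y = y0.copy()
    for a, b in zip(knots[:-1], knots[1:]):
        t_mid = (a + b) / 2.0
        mu = np.ascontiguousarray(schedule.mortality_at(t_mid))
        fert = np.ascontiguousarray(schedule.fertility_at(t_mid))
        mig = schedule.migration_at(t_mid) / 1000.0
        sig = np.ascontiguousarray(params.screening_by_age(config, t_mid))
        n_steps = max(1, int(np.ceil((b - a) / step - 1e-12)))
        y = rk4_segment(y, (b - a) / n_steps, n_steps, mu, fert, sig, lam, du,
                        cfr_d, mig, srb, g_of_age, aging)
        hit = (np.abs(eval_times - b) < 1e-9) & ~filled
        if hit.any():
            out[hit] = y
            filled |= hit
    if not filled.all():
        raise IntegrationError("internal error: some output times not covered")
    return out


def seed_disease(
    population: AgeSexGrid,
    params: ParameterSet,
    config: ModelConfig,
    *,
    mode: str = "equilibrium",
    prevalence_ceiling: float = 0.3,
) -> HealthStateGrid:
    """Deterministic initial H/U/D split at the disease introduction year.

    mode="all_healthy" puts everyone in H.  mode="equilibrium" (default)
    splits each cell at the quasi-stationary balance of the within-cell
    chain under first-period screening rates:
    U* = lam H / (sigma + mu + delta_U), D* = sigma U* / (mu + delta_D),
    capped so U + D <= prevalence_ceiling * N.  The age/sex marginal is
    preserved exactly.
    """
    t0 = config.disease_introduction_year
    if abs(population.reference_time - t0) > 1e-6:
        raise ValueError("population must be referenced at the introduction year")
    counts = np.zeros((N_AGES, 2, 3))
    if mode == "all_healthy":
        counts[:, :, 0] = population.counts
        return HealthStateGrid(counts=counts, reference_time=t0)
    if mode != "equilibrium":
        raise ValueError(f"unknown seeding mode {mode!r}")
    lam = params.incidence_by_age(config)
    sig = params.screening_by_age(config, t0)
    du = params.excess_mortality_by_age(config)
    # quasi-equilibrium fractions of the within-cell chain; background
    # mortality approximated by a flat 0.02/yr exit rate for the balance
    mu = 0.02
    u_frac = lam / (sig + mu + du)
    d_frac = sig * u_frac / (mu + params.cfr_diagnosed)
    dm = u_frac + d_frac
    scale = np.where(dm > prevalence_ceiling, prevalence_ceiling / np.maximum(dm, 1e-300), 1.0)
    u_frac, d_frac = u_frac * scale, d_frac * scale
    n = population.counts
    counts[:, :, 1] = u_frac * n
    counts[:, :, 2] = d_frac * n
    counts[:, :, 0] = n - counts[:, :, 1] - counts[:, :, 2]
    return HealthStateGrid(counts=counts, reference_time=t0)
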