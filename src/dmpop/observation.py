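"""Mapping latent trajectories to observed data streams and the likelihood.

Two data streams drive calibration:

* surveillance: reported counts of newly diagnosed diabetes per calendar
  year, sex and age group.  The model's true new diagnoses are thinned by
  the period-specific reporting proportion rho; counts are Poisson.
* surveys: diagnosed-diabetes prevalence proportions with effective sample
  sizes per survey year, sex and age group, evaluated at the survey year's
  midpoint; successes are binomial.

A small simulation cache keyed on the trajectory-relevant parameters lets
repeated likelihood calls (e.g. when only the reporting proportion moves)
reuse ODE integrations.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

from .demography import FAST_INTEGRATOR, DemographicSchedule, IntegrationError, IntegratorOptions
from .disease import DiseaseSimResult, ModelConfig, ParameterSet, simulate_disease
from .grids import SEXES, HealthStateGrid

_SURV_COLS = ["year", "sex", "age_group", "count"]
_SURVEY_COLS = ["year", "sex", "age_group", "prevalence", "n"]


@dataclass
class ObservationBundle:
    """Surveillance incident counts plus survey prevalence observations."""

    surveillance: pd.DataFrame  # year, sex, age_group, count
    surveys: pd.DataFrame       # year, sex, age_group, prevalence, n

    def __post_init__(self) -> None:
        for frame, cols, what in ((self.surveillance, _SURV_COLS, "surveillance"),
                                  (self.surveys, _SURVEY_COLS, "surveys")):
            missing = set(cols) - set(frame.columns)
            if missing:
                raise ValueError(f"{what} table missing columns {sorted(missing)}")
            bad_sex = set(frame["sex"]) - set(SEXES)
            if bad_sex:
                raise ValueError(f"{what} table has unknown sex labels {sorted(bad_sex)}")
        if len(self.surveillance) and self.surveillance["count"].min() < 0:
            raise ValueError("surveillance counts must be nonnegative")
        if len(self.surveys):
            if (self.surveys["prevalence"].min() < 0
                    or self.surveys["prevalence"].max() > 1):
                raise ValueError("survey prevalences must lie in [0, 1]")
            if self.surveys["n"].min() < 1:
                raise ValueError("survey sample sizes must be >= 1")

    @property
    def years(self) -> np.ndarray:
        ys = np.concatenate([self.surveillance["year"].to_numpy(float)
                             if len(self.surveillance) else np.empty(0),
                             self.surveys["year"].to_numpy(float)
                             if len(self.surveys) else np.empty(0)])
        return np.unique(ys)

    def to_csv(self, surveillance_path, surveys_path) -> None:
        self.surveillance.to_csv(surveillance_path, index=False)
        self.surveys.to_csv(surveys_path, index=False)

    @classmethod
    def from_csv(cls, surveillance_path, surveys_path) -> "ObservationBundle":
        return cls(surveillance=pd.read_csv(surveillance_path),
                   surveys=pd.read_csv(surveys_path))


def _group_bounds(label: str, config: ModelConfig) -> tuple[int, int]:
    try:
        gi = config.incidence_labels.index(label)
    except ValueError as err:
        raise ValueError(f"unknown age group label {label!r}") from err
    return config.incidence_groups[gi]


def group_prevalence(grid: HealthStateGrid, label: str, sex: str,
                     config: ModelConfig) -> float:
    """Diagnosed-DM prevalence D/(H+U+D) over the group's age classes."""
    lo, hi = _group_bounds(label, config)
    si = SEXES.index(sex)
    cell = grid.counts[lo:hi + 1, si, :]
    denom = cell.sum()
    if denom <= 0:
        raise ValueError(f"empty population in group {label}, sex {sex}")
    return float(cell[:, 2].sum() / denom)


def expected_observations(sim: DiseaseSimResult, params: ParameterSet,
                          bundle: ObservationBundle) -> ObservationBundle:
    """Expected values of each observation cell under the simulated model.

    Returns a bundle of the same shape whose surveillance ``count`` column
    holds rho x true diagnoses and whose survey ``prevalence`` column holds
    the model prevalence at the survey year's midpoint.
    """
    config = sim.config
    led = sim.ledger.set_index(["year", "sex", "age_group"])["true_diagnoses"]
    counts = []
    for _, row in bundle.surveillance.iterrows():
        key = (int(row["year"]), row["sex"], row["age_group"])
        if key not in led.index:
            raise KeyError(f"surveillance cell {key} outside simulated window")
        rho = params.reporting_at(config, float(row["year"]))
        counts.append(rho * float(led.loc[key]))
    surv = bundle.surveillance.copy()
    surv["count"] = counts

    prevs = []
    for _, row in bundle.surveys.iterrows():
        mid = float(row["year"]) + 0.5
        try:
            grid = sim.at(mid)
        except KeyError as err:
            raise KeyError(f"survey midpoint {mid} not simulated") from err
        prevs.append(group_prevalence(grid, row["age_group"], row["sex"], config))
    svy = bundle.surveys.copy()
    svy["prevalence"] = prevs
    return ObservationBundle(surveillance=surv, surveys=svy)


def poisson_logpmf(obs: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Continuous-in-obs Poisson log-pmf; exact at integer obs.

    mu = 0 contributes 0 when obs = 0 and -inf otherwise.
    """
    obs = np.asarray(obs, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = xlogy(obs, mu) - mu - gammaln(obs + 1.0)
    out = np.where((mu == 0) & (obs > 0), -np.inf, out)
    return out


def binomial_logpmf(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    return (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
            + xlogy(k, p) + xlogy(n - k, 1 - p))


class CalibrationContext:
    """Everything needed to evaluate the likelihood of a ParameterSet.

    Holds the initial health-state grid at the disease introduction year,
    the demographic schedule, the model configuration and the observation
    bundle; caches disease simulations keyed on the trajectory-relevant
    parameter block.
    """

    def __init__(self, initial: HealthStateGrid, schedule: DemographicSchedule,
                 config: ModelConfig, bundle: ObservationBundle,
                 integrator: IntegratorOptions | None = None,
                 cache_size: int = 32) -> None:
        self.initial = initial
        self.schedule = schedule
        self.config = config
        self.bundle = bundle
        self.integrator = integrator or FAST_INTEGRATOR
        self._cache: OrderedDict[bytes, DiseaseSimResult] = OrderedDict()
        self._cache_size = cache_size
        self.n_integration_failures = 0

        years = bundle.years
        end = (max(years.max() + 1.0, config.fit_end + 1.0)
               if years.size else config.fit_end + 1.0)
        marks = np.arange(np.ceil(initial.reference_time), np.floor(end) + 1)
        mids = (bundle.surveys["year"].to_numpy(float) + 0.5
                if len(bundle.surveys) else np.empty(0))
        self.output_years = np.unique(np.concatenate([marks, mids, [end]]))
        self._prepare_fast_path()

    def _prepare_fast_path(self) -> None:
        """Precompute index arrays mapping observation cells to simulation
        outputs, so the likelihood avoids DataFrame lookups per call."""
        config, bundle = self.config, self.bundle
        labels = list(config.incidence_labels)
        self._led_year0 = int(np.ceil(self.initial.reference_time))
        if len(bundle.surveillance):
            surv = bundle.surveillance
            self._surv_obs = surv["count"].to_numpy(float)
            yrs = surv["year"].to_numpy(int)
            self._surv_pos = yrs - self._led_year0
            self._surv_gi = np.array([labels.index(g) for g in surv["age_group"]])
            self._surv_si = np.array([SEXES.index(s) for s in surv["sex"]])
            self._surv_rho_idx = np.array([config.reporting_index(y) for y in yrs])
        if len(bundle.surveys):
            svy = bundle.surveys
            self._svy_n = svy["n"].to_numpy(float)
            self._svy_k = np.rint(svy["prevalence"].to_numpy(float) * self._svy_n)
            self._svy_gi = np.array([labels.index(g) for g in svy["age_group"]])
            self._svy_si = np.array([SEXES.index(s) for s in svy["sex"]])
            mids = svy["year"].to_numpy(float) + 0.5
            self._svy_mids = np.unique(mids)
            self._svy_mid_pos = np.searchsorted(self._svy_mids, mids)
            self._svy_grid_pos = np.searchsorted(self.output_years, self._svy_mids)
        g_of_age = config.incidence_group_of_age()
        self._G = np.zeros((len(labels), len(g_of_age)))
        self._G[g_of_age, np.arange(len(g_of_age))] = 1.0

    def simulate(self, params: ParameterSet) -> DiseaseSimResult:
        key = params.simulation_key()
        if key in self._cache:
            self._cache.move_to_end(key)
            return self._cache[key]
        sim = simulate_disease(self.initial, params, self.schedule, self.config,
                               self.output_years, integrator=self.integrator)
        self._cache[key] = sim
        if len(self._cache) > self._cache_size:
            self._cache.popitem(last=False)
        return sim

    def log_likelihood(self, params: ParameterSet) -> float:
        """Poisson (surveillance) + binomial (surveys) log-likelihood.

        Returns -inf (never raises) on integration failure so that an MCMC
        chain treats the point as impossible rather than dying.
        """
        try:
            sim = self.simulate(params)
        except IntegrationError:
            self.n_integration_failures += 1
            return -np.inf
        total = 0.0
        if len(self.bundle.surveillance):
            mu = (params.reporting[self._surv_rho_idx]
                  * sim.diagnoses_annual[self._surv_pos, self._surv_gi,
                                         self._surv_si])
            total += float(poisson_logpmf(self._surv_obs, mu).sum())
        if len(self.bundle.surveys):
            prev = np.empty((len(self._svy_mids), self._G.shape[0], 2))
            for i, pos in enumerate(self._svy_grid_pos):
                counts = sim.grids[pos].counts
                prev[i] = (self._G @ counts[:, :, 2]) / (self._G @ counts.sum(axis=2))
            p = prev[self._svy_mid_pos, self._svy_gi, self._svy_si]
            total += float(binomial_logpmf(self._svy_k, self._svy_n, p).sum())
        if np.isnan(total):
            return -np.inf
        return total
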