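# Methods

This note documents the model, its numerical treatment, the synthetic
study design, and the choices made where the design was genuinely open.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Demographic core

The population is a grid of counts over 101 annual age classes (0–100
completed years) and two sexes, evolving by ODE:

- **Aging** is a continuous linear chain at rate 1/year between adjacent
  classes. The outflow of class 100 is routed to death. A continuous chain
  (rather than an annual shift) keeps the joint system a single smooth ODE;
  the discrete cohort-component (Leslie matrix) projection is used only as
  an independent test oracle, and the two agree on 35-year totals to within
  2% in the test suite.
- **Births** enter age class 0 only, at age-specific fertility rates over
  maternal ages 15–50, split by a sex ratio at birth of 0.512 male
  (configurable; a standard demographic value, as the analysis this package
  reimplements does not state one).
- **Mortality** is an age/sex-specific hazard; **migration** is a crude
  net rate (per 1000 population per year) applied proportionally to every
  compartment, so it preserves structure.
- Fertility and mortality schedules are piecewise-constant per calendar
  decade by default; migration is piecewise-constant on its own breakpoints.

Auxiliary integrals accumulate births, deaths and net migrants alongside
the state, so `dN/dt = births − deaths + migration` is an exact identity
of the vector field and every simulation carries a conservation audit
(relative residual < 1e−6 asserted throughout the suite; in practice it is
at rounding level because the identity is linear and every integrator used
preserves linear invariants).

## Disease overlay

Each age/sex cell divides into healthy (H), undiagnosed (U) and diagnosed
(D) diabetes, with irreversible progression H→U→D:

- onset `lambda(g, s)`: per healthy person-year, constant in calendar time,
  on age groups {0–39, 40–49, 50–59, ≥60} × sex (8 parameters);
- positive screening `sigma(k, s, p)`: per undiagnosed person-year, on age
  groups {15–34, 35–59, ≥60} × sex × calendar periods {2005–2009,
  2010–2015} (12 parameters). Screening applies from age 15 (the policy
  floor); below 15 no diagnosis occurs. Before 2005 the first period's
  rates apply; after 2015 the second period's rates persist;
- undiagnosed excess case fatality `delta_U(g, s)` added to background
  mortality (8 parameters); diagnosed excess case fatality `delta_D` fixed
  at 18.4/1000 per person-year;
- reporting `rho(p)`: the proportion of true new diagnoses captured by
  surveillance, one value per period plus a pre-2005 value (3 parameters).

That totals 31 calibrated parameters plus one fixed quantity (32 model
quantities). The grouping tables and calendar anchors (disease introduced
in 2000, fit window 2005–2015, horizon 2035) live in `ModelConfig`.

Births enter H only; the status-summed system reduces exactly to the
demographic core when both excess hazards vanish (asserted to 1e−6
relative in the suite).

**Seeding.** At the introduction year each cell is split deterministically.
The default `equilibrium` mode uses the within-cell quasi-stationary
balance U* = λH/(σ+μ̃+δ_U), D* = σU*/(μ̃+δ_D) with a flat nominal exit rate
μ̃ = 0.02/yr, capped so U+D ≤ 30% of the cell — a plausible standing
prevalence for a chronic disease entering a model mid-history. An `all_healthy`
mode starts the epidemic from zero prevalence.

## Observation model and likelihood

- Expected reported counts per (year, sex, age group) are
  `rho(period) × ∫ sigma·U dt` over the calendar year, from the simulation's
  flow ledger; observed counts are Poisson.
- Expected survey prevalence is D/(H+U+D) aggregated over the group's age
  classes at the survey year's midpoint; observed prevalences contribute a
  binomial term with successes `round(prevalence × n)`.
- The likelihood is the unweighted sum of both streams (the simplest
  generative forms for count and proportion data; the source analysis does
  not state its likelihood). Noise-free synthetic bundles carry real-valued
  expected counts; the Poisson term uses the gammaln continuous extension,
  exact at integers.
- A parameter point outside support or a failed integration yields −∞
  rather than an exception, so sampler chains never die mid-run.
- Simulations are cached on the trajectory-relevant parameter block
  (everything except rho), so likelihood sweeps over reporting reuse a
  single integration.

## Priors and calibration

Priors are independent uniforms, stated explicitly because the source
analysis does not publish its priors: λ ∈ [0, 0.1]/yr, σ ∈ [0, 5]/yr,
δ_U ∈ [0, 4]/yr, ρ ∈ [0, 1].

Two samplers are provided:

- **Adaptive random-walk Metropolis** (`run_mcmc(..., sampler="metropolis")`):
  joint Gaussian proposal whose global scale follows a Robbins–Monro
  recursion toward a target acceptance rate of 0.15 during burn-in, with
  optional Haario-style covariance adaptation; both frozen after burn-in so
  the post-burn-in kernel is fixed. Chains start from prior draws (Latin
  hypercube and mode-centred options exist). Default protocol: 6 chains ×
  35,000 iterations, burn-in 5,000; the desk profile is 4 × 3,000 / 500.
- **Differential-evolution MCMC with snooker updates** (`sampler="demc"`),
  mirroring the sampler family of the R package the source analysis used:
  proposals are scaled differences of states from a growing shared history,
  so the kernel self-adapts to the posterior's correlation structure.

**Why `calibrate()` exists.** The joint posterior contains long, nearly
flat ridges: surveillance counts inform essentially the product σ·U, and
U is latent, so (λ, σ, δ_U) trade off within each age-sex block, weakly
curbed by survey prevalence and transient dynamics. A random-walk chain
started from the prior neither finds nor traverses the high-density
region at desk-scale budgets. `calibrate()` therefore runs a staged
pipeline, entirely in log-parameter space (where multiplicative ridges
straighten), with the uniform-prior Jacobian applied:

1. staged bounded quasi-Newton (L-BFGS-B) descent from the best prior
   draws, with decreasing finite-difference steps;
2. restarts against a finer-step integrator, so finite differences rise
   above the integration noise floor;
3. damped Newton iterations with an explicit finite-difference Hessian,
   absolute-value-regularized, which track the curved valley to the mode;
4. a Laplace proposal cloud (eigenvalue-floored inverse Hessian) seeding
   the final differential-evolution run, whose post-burn-in draws are
   returned on the natural scale.

The whole pipeline is deterministic given its seed.

**Diagnostics and summaries.** The Gelman–Rubin potential scale reduction
factor uses the classic between/within form
R̂ = sqrt(((n−1)/n·W + B/n)/W) on post-burn-in draws (≥ 2 chains required);
identical chains give R̂ = sqrt((n−1)/n), i.e. 1 up to O(1/n). Summaries are
medians and equal-tailed 95% intervals over pooled post-burn-in draws plus
the parameter correlation matrix; R̂ above 1.1 warns rather than fails.

## Projection

Parameter vectors are drawn without replacement from the pooled
post-burn-in chains (default 500 draws; desk profile 100); each drives one
forward simulation to the horizon, with demographic schedules held at
their last interval's values beyond coverage. Summaries are quantiles over
draws. Printed tables report counts in thousands with cells rounded to the
nearest 10 thousand and row totals computed as the sum of the rounded
cells, so the printed row identity holds exactly.

## Synthetic study design

The generator emulates the structure of a national census, a household
health-examination survey series, and chronic-disease surveillance
reports, none of which are redistributable:

- census-like 1980 pyramid: exponential-in-age shape with a smooth seeded
  wiggle; default total 4.7 million (~1/10 national scale, so the full
  pipeline runs in minutes; `ScenarioSpec.paper_scale()` restores ~47M);
- decade-constant schedules: a fertility hump over ages 15–50 with total
  fertility declining 0.5 births/woman per decade from 3.4 (floor 1.5);
  Gompertz adult mortality (2e−4·e^{0.085·age}) with an infant component,
  30% male excess, and a 0.9×/decade improvement; constant net migration
  +0.6/1000/yr;
- ground-truth disease parameters at realistic magnitudes: peak incidence
  330/10,000 person-years (women 50–59), male screening rates rising
  ten-fold with age (0.06 → 1.11/yr), female screening highest at ages
  15–34 early and falling later, reporting 80 → 87.4%, undiagnosed case
  fatality about ten-fold the diagnosed 18.4/1000 (3.0/yr below age 40,
  reading the "per 6 months" unit as a rate and doubling it to per-year);
- observation noise: Poisson on thinned counts; binomial on survey
  prevalences at n = 3,000 per (year, sex, age group) cell — a plausible
  effective size for a national examination survey stratum, chosen because
  the real survey sizes are not stated per cell.

What the generator does **not** emulate: secular trends in incidence,
reporting heterogeneity by region or provider, survey design effects,
age misstatement, or migration age profiles. Passing tests therefore
demonstrate the correctness of the machinery under the model's own
assumptions, not robustness to real-data violations of them.

**Recovery harness.** Under the default (equilibrium-seeded) scenario the
ridge described above makes (λ, σ, δ_U) only jointly identified — a
property of the observation design, not a code defect. Parameter-recovery
validation therefore uses `recovery_scenario()`: everyone healthy at the
2000 introduction, observations from 2001, surveys every third year at
n = 20,000, noise off. The epidemic's build-up separates the onset,
detection and mortality time scales, and the calibration pipeline then
recovers the generating values (the acceptance suite asserts ≥ 90% of the
31 true values inside their 95% intervals, and correct signs of the
posterior correlation structure). The pre-2005 reporting proportion has no
surveillance data to inform it under either design; its posterior
reproduces the prior, and the reporting-recovery check applies to the two
data-covered periods.

## Numerical choices

- Standalone simulations: scipy `solve_ivp`, LSODA (stiff-capable via
  automatic switching), rtol 1e−8 / atol 1e−10, integrated piecewise
  between schedule breakpoints so the right-hand side is smooth per
  segment.
- Calibration likelihood: a numba-compiled fixed-step RK4 integrator
  (step 0.1 yr; the fastest rate in support is ≈ 11/yr, well inside RK4's
  stability region), about 6 ms per 16-year forward run versus ~25 ms for
  the adaptive solvers, whose per-step overhead dominates at this system
  size. Agreement with the reference solver is ~1e−3 in log-likelihood
  units, far below posterior scale. Mode refinement uses a 4× finer step.
- Output counts are clipped to zero when negative by less than
  1e−7 × total population (transport undershoot at empty compartments);
  anything more negative raises. Clipping applies to output copies only,
  never to the integrator state, so conservation audits are unaffected.
- Ties and degenerate inputs: empty populations raise on prevalence/share
  computations; zero screening gives an infinite mean time to diagnosis;
  degenerate (single-draw) posteriors give zero-width intervals.

## Limitations

- Incidence and case-fatality rates are constant in calendar time within
  the fitted structure; secular improvement in survival or lifestyle-driven
  incidence trends are out of scope, as are pre-diabetes states, remission,
  type 1/type 2 distinction, and behavioural covariates.
- The likelihood assumes independent Poisson/binomial observations;
  over-dispersion hooks exist in the code but are off by default.
- Identifiability of (λ, σ, δ_U) separately rests on transient information;
  analyses fitted entirely in quasi-steady state should interpret those
  marginals — and the reporting proportion, which trades off against the
  simulated diagnosis level — as prior-and-ridge constrained, and rely on
  the data-anchored functionals (prevalence trajectories and their
  projections).
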