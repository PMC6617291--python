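"""Bayesian MCMC calibration of the 31 free model parameters.

The sampler is an adaptive random-walk Metropolis with a joint Gaussian
proposal.  During burn-in the global proposal scale follows a
Robbins-Monro recursion toward a target acceptance rate (0.15 by default)
and, optionally, the proposal covariance adapts to the running empirical
covariance of the chain; both are frozen after burn-in so the
post-burn-in kernel is a fixed Metropolis kernel.

Convergence is monitored with the between/within-chain potential scale
reduction factor; summaries are medians, equal-tailed credible intervals
and the parameter correlation matrix over pooled post-burn-in draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .disease import ModelConfig, ParameterSet
from .observation import CalibrationContext

DEFAULT_TARGET_ACCEPT = 0.15


class DiagnosticFailure(RuntimeError):
    """All chains effectively stuck (vanishing acceptance after burn-in)."""


@dataclass
class PriorSpec:
    """Independent priors per free parameter: uniform or log-uniform boxes."""

    lower: np.ndarray
    upper: np.ndarray
    names: list[str]
    log_scale: np.ndarray | None = None  # bool per parameter; default all False

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.log_scale is None:
            self.log_scale = np.zeros(len(self.lower), dtype=bool)
        self.log_scale = np.asarray(self.log_scale, dtype=bool)
        if not (len(self.lower) == len(self.upper) == len(self.names)
                == len(self.log_scale)):
            raise ValueError("prior arrays must have equal lengths")
        if not np.all(np.isfinite(self.lower) & np.isfinite(self.upper)):
            raise ValueError("prior bounds must be finite")
        if np.any(self.lower >= self.upper):
            raise ValueError("prior lower bounds must be below upper bounds")
        if np.any(self.log_scale & (self.lower <= 0)):
            raise ValueError("log-uniform priors require positive lower bounds")

    @property
    def dim(self) -> int:
        return len(self.lower)

    def in_support(self, x: np.ndarray) -> bool:
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))

    def logpdf(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if not self.in_support(x):
            return -np.inf
        out = -np.sum(np.log(self.upper - self.lower)[~self.log_scale])
        if self.log_scale.any():
            ls = self.log_scale
            out += -np.sum(np.log(x[ls]) + np.log(np.log(self.upper[ls] / self.lower[ls])))
        return float(out)

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        u = rng.uniform(size=(n, self.dim))
        return self._from_unit(u)

    def sample_lhs(self, rng: np.random.Generator, n: int) -> np.ndarray:
        sampler = qmc.LatinHypercube(d=self.dim, seed=rng)
        return self._from_unit(sampler.random(n))

    def _from_unit(self, u: np.ndarray) -> np.ndarray:
        x = self.lower + u * (self.upper - self.lower)
        if self.log_scale.any():
            ls = self.log_scale
            x[:, ls] = self.lower[ls] * np.exp(
                u[:, ls] * np.log(self.upper[ls] / self.lower[ls]))
        return x

    @classmethod
    def default(cls, config: ModelConfig | None = None) -> "PriorSpec":
        """Uniform boxes: incidence [0, 0.1]/yr, screening [0, 5]/yr,
        undiagnosed excess mortality [0, 4]/yr, reporting [0, 1]."""
        config = config or ModelConfig()
        names = ParameterSet.calibrated_names(config)
        lower = np.zeros(31)
        upper = np.concatenate([np.full(8, 0.1), np.full(12, 5.0),
                                np.full(8, 4.0), np.full(3, 1.0)])
        return cls(lower=lower, upper=upper, names=names)


@dataclass
class PosteriorChains:
    """Multi-chain MCMC draws over the sampled (free) parameters."""

    draws: np.ndarray          # (n_chains, n_iter, n_free)
    log_posts: np.ndarray      # (n_chains, n_iter)
    burn_in: int
    acceptance_rates: np.ndarray  # per chain, post-burn-in
    free_names: list[str]
    seed: int
    template: ParameterSet | None = None  # carries fixed values (incl. cfr)
    free_mask: np.ndarray | None = None   # bool (31,) if template is set

    def __post_init__(self) -> None:
        c, i, p = self.draws.shape
        if self.burn_in >= i:
            raise ValueError("burn-in must be shorter than the chain")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def post_burn_in(self) -> np.ndarray:
        """(n_chains, n_kept, n_free) draws with burn-in removed."""
        return self.draws[:, self.burn_in:, :]

    def pooled(self) -> np.ndarray:
        kept = self.post_burn_in()
        return kept.reshape(-1, kept.shape[-1])

    def parameter_set(self, free_values: np.ndarray) -> ParameterSet:
        """Reconstruct a full ParameterSet from one draw of the free block."""
        if self.template is None:
            raise ValueError("chains carry no ParameterSet template")
        vec = self.template.to_vector()
        mask = (np.ones(31, dtype=bool) if self.free_mask is None
                else self.free_mask)
        vec[mask] = free_values
        return ParameterSet.from_vector(vec, cfr_diagnosed=self.template.cfr_diagnosed)

    def to_csv(self, chains_path, metadata_path=None) -> None:
        c, i, p = self.draws.shape
        frame = pd.DataFrame({
            "chain": np.repeat(np.arange(1, c + 1), i * p),
            "iteration": np.tile(np.repeat(np.arange(1, i + 1), p), c),
            "parameter": np.tile(self.free_names, c * i),
            "value": self.draws.ravel(),
        })
        frame.to_csv(chains_path, index=False)
        if metadata_path is not None:
            meta = {
                "seed": int(self.seed), "burn_in": int(self.burn_in),
                "n_chains": int(c), "n_iterations": int(i),
                "acceptance_rates": [float(a) for a in self.acceptance_rates],
                "free_names": list(self.free_names),
            }
            with open(metadata_path, "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def from_csv(cls, chains_path, metadata_path) -> "PosteriorChains":
        with open(metadata_path) as fh:
            meta = json.load(fh)
        frame = pd.read_csv(chains_path)
        names = meta["free_names"]
        c, i, p = meta["n_chains"], meta["n_iterations"], len(names)
        draws = np.empty((c, i, p))
        piv = frame.pivot_table(index=["chain", "iteration"], columns="parameter",
                                values="value", sort=False)
        piv = piv[names]
        draws = piv.to_numpy().reshape(c, i, p)
        return cls(draws=draws, log_posts=np.zeros((c, i)),
                   burn_in=meta["burn_in"],
                   acceptance_rates=np.array(meta["acceptance_rates"]),
                   free_names=names, seed=meta["seed"])


def adaptive_metropolis(
    log_prob,
    x0: np.ndarray,
    n_iter: int,
    burn_in: int,
    rng: np.random.Generator,
    *,
    target_accept: float = DEFAULT_TARGET_ACCEPT,
    cov0: np.ndarray | None = None,
    adapt_cov: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One adaptive random-walk Metropolis chain.

    Returns (draws (n_iter, p), log-probabilities, post-burn-in acceptance).
    Scale and covariance adaptation run during burn-in only.
    """
    x = np.asarray(x0, dtype=float).copy()
    p = len(x)
    lp = float(log_prob(x))
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log-probability")
    cov = np.eye(p) if cov0 is None else np.asarray(cov0, dtype=float)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    log_scale = np.log(2.38 / np.sqrt(p))
    draws = np.empty((n_iter, p))
    lps = np.empty(n_iter)
    mean = x.copy()
    m2 = np.zeros((p, p))
    accepted_post = 0
    for i in range(n_iter):
        z = rng.standard_normal(p)
        proposal = x + np.exp(log_scale) * (chol @ z)
        lp_prop = float(log_prob(proposal))
        log_alpha = lp_prop - lp
        alpha = np.exp(min(0.0, log_alpha)) if np.isfinite(lp_prop) else 0.0
        if rng.uniform() < alpha:
            x, lp = proposal, lp_prop
            if i >= burn_in:
                accepted_post += 1
        draws[i] = x
        lps[i] = lp
        if i < burn_in:
            log_scale += 2.0 / (i + 1.0) ** 0.6 * (alpha - target_accept)
            delta = x - mean
            mean += delta / (i + 2)
            m2 += np.outer(delta, x - mean)
            if adapt_cov and i >= max(100, 2 * p) and (i + 1) % 25 == 0:
                emp = m2 / (i + 1)
                chol = np.linalg.cholesky(emp + 1e-8 * np.eye(p)
                                          * max(np.trace(emp) / p, 1e-12))
    accept_rate = accepted_post / max(n_iter - burn_in, 1)
    return draws, lps, accept_rate


def demc_sample(
    log_prob,
    starts: np.ndarray,
    n_iter: int,
    burn_in: int,
    rng: np.random.Generator,
    *,
    prior_pool: np.ndarray,
    gamma_jump_every: int = 10,
    snooker_prob: float = 0.1,
    history_thin: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Differential-evolution MCMC with snooker updates (DE-MCzs).

    Proposals are built from differences of states in a growing shared
    history, so the kernel self-adapts to the posterior's correlation
    structure and mixes along ridges that defeat a random-walk kernel.
    The history is seeded with ``prior_pool`` draws and extended with the
    ensemble's own states every ``history_thin`` iterations.

    Returns (draws (n_chains, n_iter, p), log-probs, post-burn-in
    acceptance rates per chain).
    """
    x = np.array(starts, dtype=float)           # (n_chains, p)
    n_chains, p = x.shape
    lp = np.array([log_prob(xi) for xi in x])
    if not np.all(np.isfinite(lp)):
        raise ValueError("all starting points must have finite log-probability")
    z = list(np.asarray(prior_pool, dtype=float))
    gamma0 = 2.38 / np.sqrt(2 * p)
    draws = np.empty((n_chains, n_iter, p))
    lps = np.empty((n_chains, n_iter))
    accepted = np.zeros(n_chains, dtype=int)
    for i in range(n_iter):
        for c in range(n_chains):
            m = len(z)
            prop = None
            if rng.uniform() < snooker_prob:
                # snooker update along the direction to a random history point
                zi, z1, z2 = (z[j] for j in rng.choice(m, size=3, replace=False))
                d = x[c] - zi
                norm2 = d @ d
                if norm2 > 0:
                    gamma_s = rng.uniform(1.2, 2.2)
                    proj = lambda v: (v @ d) / norm2 * d
                    prop = x[c] + gamma_s * (proj(z1) - proj(z2))
                    dist_ratio = np.linalg.norm(prop - zi) / np.sqrt(norm2)
                    log_metric = (p - 1) * np.log(max(dist_ratio, 1e-300))
            else:
                j1, j2 = rng.choice(m, size=2, replace=False)
                gamma = 0.98 if (i % gamma_jump_every) == gamma_jump_every - 1 \
                    else gamma0
                prop = x[c] + gamma * (z[j1] - z[j2]) \
                    + 1e-6 * rng.standard_normal(p)
                log_metric = 0.0
            if prop is not None:
                lp_prop = float(log_prob(prop))
                if np.isfinite(lp_prop) and np.log(rng.uniform()) < (
                        lp_prop - lp[c] + log_metric):
                    x[c], lp[c] = prop, lp_prop
                    if i >= burn_in:
                        accepted[c] += 1
            draws[c, i] = x[c]
            lps[c, i] = lp[c]
        if (i + 1) % history_thin == 0:
            z.extend(x.copy())
    accept = accepted / max(n_iter - burn_in, 1)
    return draws, lps, accept


def _find_mode(log_prob, priors: PriorSpec, free_idx: np.ndarray,
               rng: np.random.Generator, n_starts: int = 16) -> np.ndarray:
    """Rough posterior-mode search: best prior draw refined by Nelder-Mead."""
    starts = priors.sample(rng, n_starts)[:, free_idx]
    lps = np.array([log_prob(s) for s in starts])
    best = starts[int(np.argmax(lps))]
    res = minimize(lambda v: -log_prob(v), best, method="Nelder-Mead",
                   options={"maxfev": 4000, "xatol": 1e-6, "fatol": 1e-6})
    return res.x if np.isfinite(res.fun) else best


def run_mcmc(
    context: CalibrationContext,
    priors: PriorSpec,
    *,
    n_chains: int = 6,
    n_iter: int = 35000,
    burn_in: int = 5000,
    seed: int = 0,
    target_accept: float = DEFAULT_TARGET_ACCEPT,
    fixed: dict[str, float] | None = None,
    init: str = "prior",
    adapt_cov: bool = True,
    sampler: str = "metropolis",
    cfr_diagnosed: float | None = None,
) -> PosteriorChains:
    """Calibrate the model over the free parameters (those not pinned via
    ``fixed``).

    sampler: "metropolis" (adaptive random-walk, scale tuned to the target
    acceptance rate) or "demc" (differential-evolution ensemble with
    snooker updates, better along posterior ridges).
    init: "prior" (independent prior draws), "lhs" (latin hypercube) or
    "map" (mode search followed by small per-chain jitter).
    """
    if priors.names != ParameterSet.calibrated_names(context.config):
        raise ValueError("prior names must match the canonical parameter ordering")
    fixed = dict(fixed or {})
    unknown = set(fixed) - set(priors.names)
    if unknown:
        raise ValueError(f"fixed parameters not in the model: {sorted(unknown)}")
    free_mask = np.array([n not in fixed for n in priors.names])
    free_idx = np.flatnonzero(free_mask)
    free_names = [priors.names[i] for i in free_idx]
    base = np.zeros(31)
    for name, val in fixed.items():
        base[priors.names.index(name)] = val
    from .disease import DIAGNOSED_CASE_FATALITY
    cfr = DIAGNOSED_CASE_FATALITY if cfr_diagnosed is None else cfr_diagnosed

    def log_prob(free: np.ndarray) -> float:
        vec = base.copy()
        vec[free_idx] = free
        # prior over the free block only (fixed block is conditioned on)
        if not (np.all(free >= priors.lower[free_idx])
                and np.all(free <= priors.upper[free_idx])):
            return -np.inf
        lp = -float(np.sum(np.log((priors.upper - priors.lower)[free_idx])))
        try:
            params = ParameterSet.from_vector(vec, cfr_diagnosed=cfr)
        except ValueError:
            return -np.inf
        return lp + context.log_likelihood(params)

    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    chain_seeds = ss.spawn(n_chains + 1)[1:]

    widths = (priors.upper - priors.lower)[free_idx]
    cov0 = np.diag((widths / 50.0) ** 2)
    if init == "map":
        mode = _find_mode(log_prob, priors, free_idx, master)
        starts = []
        for _ in range(n_chains):
            for _ in range(200):
                cand = mode + master.standard_normal(len(free_idx)) * widths / 200.0
                cand = np.clip(cand, priors.lower[free_idx], priors.upper[free_idx])
                if np.isfinite(log_prob(cand)):
                    starts.append(cand)
                    break
            else:
                raise ValueError("could not jitter a finite start around the mode")
    else:
        draw_fn = priors.sample_lhs if init == "lhs" else priors.sample
        starts = []
        pool = draw_fn(master, max(4 * n_chains, 16))[:, free_idx]
        for cand in pool:
            if np.isfinite(log_prob(cand)):
                starts.append(cand)
            if len(starts) == n_chains:
                break
        if len(starts) < n_chains:
            raise ValueError("could not find enough finite-posterior starts")

    if sampler == "demc":
        pool = priors.sample(master, max(10 * len(free_idx), 64))[:, free_idx]
        rng = np.random.default_rng(chain_seeds[0])
        stacked, lps, accepts = demc_sample(log_prob, np.array(starts), n_iter,
                                            burn_in, rng, prior_pool=pool)
        all_draws, all_lps = list(stacked), list(lps)
    elif sampler == "metropolis":
        all_draws, all_lps, accepts = [], [], []
        for c in range(n_chains):
            rng = np.random.default_rng(chain_seeds[c])
            draws, lps, acc = adaptive_metropolis(
                log_prob, starts[c], n_iter, burn_in, rng,
                target_accept=target_accept, cov0=cov0, adapt_cov=adapt_cov)
            all_draws.append(draws)
            all_lps.append(lps)
            accepts.append(acc)
    else:
        raise ValueError(f"unknown sampler {sampler!r}")
    accepts = np.asarray(accepts, dtype=float)
    if np.all(accepts < 1e-3):
        raise DiagnosticFailure(
            f"all chains stuck: post-burn-in acceptance {accepts.tolist()}")

    template = ParameterSet.from_vector(base, cfr_diagnosed=cfr)
    return PosteriorChains(draws=np.stack(all_draws), log_posts=np.stack(all_lps),
                           burn_in=burn_in, acceptance_rates=accepts,
                           free_names=free_names, seed=seed,
                           template=template, free_mask=free_mask)


def calibrate(
    context: CalibrationContext,
    priors: PriorSpec,
    *,
    n_chains: int = 4,
    n_iter: int = 16000,
    burn_in: int = 5000,
    n_starts: int = 2,
    newton_iter: int = 15,
    seed: int = 0,
    fixed: dict[str, float] | None = None,
    cfr_diagnosed: float | None = None,
) -> PosteriorChains:
    """Full-strength calibration for the joint 31-parameter posterior.

    The posterior has long, nearly flat ridges (only the product of the
    positive-screening rate and the latent undiagnosed pool is strongly
    informed by surveillance counts), so a plain random-walk chain started
    from the prior neither finds nor traverses the high-density region.
    This routine therefore runs a staged pipeline, all in log-parameter
    space where the ridges straighten:

    1. mode search: best prior draws refined by staged bounded quasi-Newton
       (L-BFGS-B) passes with decreasing finite-difference steps, then
       restarted against a finer-step integrator so the finite differences
       rise above the integration noise floor;
    2. damped Newton iterations with an explicit finite-difference Hessian
       (absolute-value regularized), which follow the curved valley the
       quasi-Newton passes stall in;
    3. Laplace preconditioning: the Hessian at the mode, eigenvalue-floored,
       shapes the initial proposal cloud;
    4. the final differential-evolution run with snooker updates, whose
       post-burn-in draws (mapped back to natural scale) are returned.

    Deterministic given ``seed``.  ``fixed`` pins named parameters at given
    values, exactly as in :func:`run_mcmc`.
    """
    from .disease import DIAGNOSED_CASE_FATALITY

    if priors.names != ParameterSet.calibrated_names(context.config):
        raise ValueError("prior names must match the canonical parameter ordering")
    fixed = dict(fixed or {})
    free_mask = np.array([n not in fixed for n in priors.names])
    free_idx = np.flatnonzero(free_mask)
    free_names = [priors.names[i] for i in free_idx]
    p = len(free_idx)
    cfr = DIAGNOSED_CASE_FATALITY if cfr_diagnosed is None else cfr_diagnosed
    base = np.zeros(31)
    for name, val in fixed.items():
        base[priors.names.index(name)] = val

    hi = priors.upper[free_idx]
    log_hi = np.log(hi)
    log_floor = np.log(1e-6 * np.maximum(hi, 1e-6))

    def _ll(free: np.ndarray) -> float:
        vec = base.copy()
        vec[free_idx] = free
        try:
            params = ParameterSet.from_vector(vec, cfr_diagnosed=cfr)
        except ValueError:
            return -np.inf
        return context.log_likelihood(params)

    def log_post_v(v: np.ndarray) -> float:
        if np.any(v > log_hi) or np.any(v < log_floor):
            return -np.inf
        ll = _ll(np.exp(v))
        # log-space Jacobian under the uniform natural-scale prior
        return ll + float(v.sum()) if np.isfinite(ll) else -np.inf

    def neg_ll_v(v: np.ndarray) -> float:
        val = _ll(np.minimum(np.exp(v), hi))
        return -val if np.isfinite(val) else 1e10

    # finer-step twin of the likelihood for mode refinement: the fixed-step
    # integration noise must sit below the finite-difference increments
    from .observation import CalibrationContext

    if context.integrator.method == "rk4":
        from dataclasses import replace as _replace

        fine_ctx = CalibrationContext(
            context.initial, context.schedule, context.config, context.bundle,
            integrator=_replace(context.integrator,
                                step=context.integrator.step / 4.0))

        def neg_ll_fine(v: np.ndarray) -> float:
            x = np.minimum(np.exp(v), hi)
            vec = base.copy()
            vec[free_idx] = x
            try:
                params = ParameterSet.from_vector(vec, cfr_diagnosed=cfr)
            except ValueError:
                return 1e10
            val = fine_ctx.log_likelihood(params)
            return -val if np.isfinite(val) else 1e10
    else:
        neg_ll_fine = neg_ll_v

    bounds = list(zip(log_floor, log_hi))

    def grad_and_hessian(fn, v, h=0.01):
        ei = np.eye(p) * h
        f0 = fn(v)
        f_plus = np.array([fn(v + ei[i]) for i in range(p)])
        f_minus = np.array([fn(v - ei[i]) for i in range(p)])
        grad = (f_plus - f_minus) / (2 * h)
        hess = np.zeros((p, p))
        for i in range(p):
            hess[i, i] = (f_plus[i] - 2 * f0 + f_minus[i]) / h ** 2
            for j in range(i + 1, p):
                fij = fn(v + ei[i] + ei[j])
                hess[i, j] = hess[j, i] = (fij - f_plus[i] - f_plus[j] + f0) / h ** 2
        return f0, grad, (hess + hess.T) / 2

    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))

    # stage 1: staged quasi-Newton descent from the best prior draws
    pool = np.clip(priors.sample(rng, 30)[:, free_idx], np.exp(log_floor), hi)
    pool_vals = np.array([neg_ll_v(np.log(x)) for x in pool])
    order = np.argsort(pool_vals)
    best_v, best_f = None, np.inf
    for k in order[:n_starts]:
        v = np.log(pool[k])
        f = pool_vals[k]
        for eps, maxiter in ((3e-3, 80), (1e-3, 80), (3e-4, 100)):
            res = minimize(neg_ll_v, v, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": maxiter, "eps": eps})
            v, f = res.x, res.fun
        if f < best_f:
            best_v, best_f = v, f
    # restarts against the low-noise objective
    best_f = neg_ll_fine(best_v)
    prev = np.inf
    for r in range(6):
        res = minimize(neg_ll_fine, best_v, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 120, "eps": (3e-4, 1e-4)[r % 2]})
        if res.fun < best_f:
            best_v, best_f = res.x, res.fun
        if prev - best_f < 0.2:
            break
        prev = best_f

    # stage 2: damped Newton with an explicit regularized Hessian
    hess = np.eye(p)
    for _ in range(newton_iter):
        f0, grad, hess = grad_and_hessian(neg_ll_fine, best_v)
        w, vec = np.linalg.eigh(hess)
        step = -(vec / np.clip(np.abs(w), 0.05, None)) @ (vec.T @ grad)
        improved = False
        for damp in (1.0, 0.5, 0.25, 0.1, 0.04):
            cand = np.clip(best_v + damp * step, log_floor, log_hi)
            fc = neg_ll_fine(cand)
            if fc < f0 - 1e-3:
                best_v, best_f = cand, fc
                improved = True
                break
        if not improved or f0 - best_f < 0.02:
            break

    # stage 3-4: Laplace-shaped cloud, final differential-evolution run
    w, vec = np.linalg.eigh(hess)
    chol = vec / np.sqrt(np.clip(w, 0.1, None))
    cloud = best_v + (chol @ rng.standard_normal((p, 400))).T
    starts = []
    while len(starts) < n_chains:
        cand = best_v + chol @ rng.standard_normal(p)
        if np.isfinite(log_post_v(cand)):
            starts.append(cand)
    starts = np.array(starts)
    draws_v, lps, accepts = demc_sample(log_post_v, starts, n_iter, burn_in,
                                        rng, prior_pool=cloud)
    draws = np.exp(draws_v)
    template = ParameterSet.from_vector(base, cfr_diagnosed=cfr)
    return PosteriorChains(draws=draws, log_posts=lps, burn_in=burn_in,
                           acceptance_rates=np.asarray(accepts, dtype=float),
                           free_names=free_names, seed=seed,
                           template=template, free_mask=free_mask)


# ------------------------------------------------------------- diagnostics

def gelman_rubin(chains: PosteriorChains | np.ndarray,
                 burn_in: int | None = None) -> pd.Series:
    """Potential scale reduction factor per parameter (between/within form).

    R-hat = sqrt(((n-1)/n W + B/n) / W) on post-burn-in draws.
    """
    if isinstance(chains, PosteriorChains):
        draws = chains.post_burn_in()
        names = chains.free_names
    else:
        draws = np.asarray(chains, dtype=float)
        if burn_in:
            draws = draws[:, burn_in:, :]
        names = [f"p{i}" for i in range(draws.shape[2])]
    m, n, p = draws.shape
    if m < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    if n < 10:
        raise ValueError("Gelman-Rubin requires at least 10 post-burn-in draws")
    chain_means = draws.mean(axis=1)                      # (m, p)
    w = draws.var(axis=1, ddof=1).mean(axis=0)            # within
    b = n * chain_means.var(axis=0, ddof=1)               # between
    var_plus = (n - 1) / n * w + b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / w)
    rhat = np.where(w == 0, 1.0, rhat)
    return pd.Series(rhat, index=names, name="rhat")


def posterior_summary(chains: PosteriorChains, *, credible: float = 0.95,
                      rhat_threshold: float = 1.1,
                      warn: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Medians, equal-tailed credible intervals and correlation matrix.

    Returns (summary frame indexed by parameter, correlation matrix frame).
    Convergence violations warn rather than fail.
    """
    import warnings

    pooled = chains.pooled()
    names = chains.free_names
    if warn and chains.n_chains >= 2 and chains.draws.shape[1] - chains.burn_in >= 10:
        rhat = gelman_rubin(chains)
        bad = rhat[rhat > rhat_threshold]
        if len(bad):
            warnings.warn(f"R-hat above {rhat_threshold} for: "
                          f"{dict(bad.round(3))}", stacklevel=2)
    tail = (1.0 - credible) / 2.0
    lo, med, hi = np.quantile(pooled, [tail, 0.5, 1.0 - tail], axis=0)
    summary = pd.DataFrame({"median": med, "lower": lo, "upper": hi}, index=names)
    sd = pooled.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(pooled, rowvar=False)
    if np.ndim(corr) == 0:  # single parameter
        corr = np.array([[1.0]])
    corr = np.where(np.outer(sd == 0, sd == 0), 0.0, corr)
    np.fill_diagonal(corr, 1.0)
    corr_frame = pd.DataFrame(corr, index=names, columns=names)
    return summary, corr_frame


def parameter_recovery_report(truth: ParameterSet | np.ndarray,
                              chains: PosteriorChains,
                              priors: PriorSpec | None = None) -> pd.DataFrame:
    """Coverage and relative-error table against known ground truth."""
    if isinstance(truth, ParameterSet):
        truth_vec = truth.to_vector()
        all_names = ParameterSet.calibrated_names()
        truth_map = dict(zip(all_names, truth_vec))
    else:
        truth_vec = np.asarray(truth, dtype=float)
        if len(truth_vec) == len(chains.free_names):
            truth_map = dict(zip(chains.free_names, truth_vec))
        else:
            truth_map = dict(zip(ParameterSet.calibrated_names(), truth_vec))
    summary, _ = posterior_summary(chains, warn=False)
    rows = []
    for name in chains.free_names:
        true_val = truth_map[name]
        med, lo, hi = summary.loc[name, ["median", "lower", "upper"]]
        covered = bool(lo - 1e-12 <= true_val <= hi + 1e-12)
        denom = abs(true_val) if true_val != 0 else 1.0
        rel_err = abs(med - true_val) / denom
        at_bound = False
        if priors is not None:
            i = priors.names.index(name)
            span = priors.upper[i] - priors.lower[i]
            at_bound = (abs(true_val - priors.lower[i]) < 1e-9 * span
                        or abs(true_val - priors.upper[i]) < 1e-9 * span)
        rows.append((name, true_val, med, lo, hi, covered, rel_err, at_bound))
    return pd.DataFrame(rows, columns=["parameter", "truth", "median", "lower",
                                       "upper", "covered", "rel_error",
                                       "truth_at_prior_bound"])
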