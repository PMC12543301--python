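"""Per-participant Bayesian estimation of the learning models.

Two fitting routes share one posterior:

* ``method="mcmc"`` — the canonical route: seeded affine-invariant ensemble
  sampling (emcee) with the study's draw bookkeeping (3 chains-worth of 2400
  kept draws after 1000 burn-in steps, thinned by 3, by default), R-hat and
  effective-sample-size diagnostics via arviz.
* ``method="map"`` — a fast deterministic route: multi-start bound-constrained
  MAP optimization followed by a Laplace (Gaussian) approximation whose draws
  stand in for posterior samples.  Clearly approximate; used where speed
  matters (recovery experiments, smoke tests).

Priors are weakly informative and bounded: alpha, w ~ Uniform(0, 1),
SV ~ Uniform(0, 100), sigma ~ half-normal(scale 20).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_space import (
    DEFAULT_SIGMA_ND, ModelSpec, cells_from_frame, pointwise_loglik, predict_cell,
)


@dataclass(frozen=True)
class FitConfig:
    """Sampling and optimization settings.

    ``n_burnin`` counts sampler steps, ``n_kept`` the total number of retained
    posterior draws after thinning by ``thin`` (the kept draws divide evenly
    over chains/walkers).  ``n_starts`` and ``n_laplace_draws`` only affect the
    MAP route.
    """

    n_chains: int = 3
    n_burnin: int = 1000
    n_kept: int = 2400
    thin: int = 3
    seed: int = 0
    n_starts: int = 4
    n_laplace_draws: int = 600
    sigma_nd: float = DEFAULT_SIGMA_ND

    def __post_init__(self):
        for name in ("n_chains", "n_burnin", "n_kept", "thin"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class PosteriorSummary:
    """Posterior draws and summaries for one participant x model fit."""

    model_id: str
    method: str
    param_names: tuple
    mean: np.ndarray
    sd: np.ndarray
    rhat: np.ndarray
    n_eff: np.ndarray
    draws: np.ndarray          # (n_kept, P)
    loglik: np.ndarray         # (n_kept, n_trials)
    flags: list = field(default_factory=list)
    map_estimate: np.ndarray | None = None

    @property
    def means(self) -> dict:
        return dict(zip(self.param_names, self.mean))

    def summary_dict(self) -> dict:
        return {
            "model": self.model_id,
            "method": self.method,
            "flags": list(self.flags),
            "params": {
                n: {"mean": float(m), "sd": float(s),
                    "rhat": float(r), "n_eff": float(e)}
                for n, m, s, r, e in zip(
                    self.param_names, self.mean, self.sd, self.rhat, self.n_eff)
            },
        }


# ---------------------------------------------------------------------------
# posterior density
# ---------------------------------------------------------------------------

def log_prior(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])
    inside = np.all((theta >= lo) & (theta <= hi), axis=1)
    sigma = theta[:, spec.sigma_index]
    with np.errstate(invalid="ignore"):
        lp = -0.5 * (sigma / 20.0) ** 2
    return np.where(inside, lp, -np.inf)


def log_posterior(spec: ModelSpec, theta: np.ndarray, cells,
                  sigma_nd: float = DEFAULT_SIGMA_ND) -> np.ndarray:
    """Unnormalized log posterior, batched over parameter vectors (B,)."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    lp = log_prior(spec, theta)
    out = np.full(theta.shape[0], -np.inf)
    ok = np.isfinite(lp)
    if np.any(ok):
        ll = pointwise_loglik(spec, theta[ok], cells, sigma_nd).sum(axis=1)
        out[ok] = ll + lp[ok]
    return out


# ---------------------------------------------------------------------------
# MAP + Laplace route
# ---------------------------------------------------------------------------

def _data_driven_start(spec: ModelSpec, cells) -> np.ndarray:
    theta = np.empty(spec.n_params)
    first = {}
    cellmean = {}
    resid_sd = []
    for c in cells:
        first[(c.session, c.agent, c.ability)] = float(np.clip(c.observed[0], 2, 98))
        cellmean[(c.session, c.agent, c.ability)] = float(np.clip(c.observed.mean(), 2, 98))
        if len(c.observed) > 1:
            resid_sd.append(np.std(np.diff(c.observed)) / math.sqrt(2))
    sigma0 = float(np.clip(np.mean(resid_sd) if resid_sd else 10.0, 3.0, 30.0))
    for i, name in enumerate(spec.param_names):
        if name.startswith("alpha"):
            theta[i] = 0.3
        elif name.startswith("w_"):
            theta[i] = 0.2
        elif name.startswith(("sv_", "mean_")):
            _, s, a, b = name.split("_")
            src = cellmean if spec.mean_model else first
            theta[i] = src.get((s, a, b), 50.0)
        else:  # sigma
            theta[i] = sigma0
    return theta


def _value_and_grad(f_batch, lo, hi):
    h = 1e-6 * (hi - lo)

    def fg(x):
        sign = np.where(x + h > hi, -1.0, 1.0)
        pts = np.vstack([x, x[None, :] + np.diag(sign * h)])
        vals = f_batch(pts)
        grad = sign * (vals[1:] - vals[0]) / h
        return vals[0], grad

    return fg


def fit_map(spec: ModelSpec, trials, config: FitConfig = FitConfig()) -> tuple:
    """Multi-start bound-constrained MAP estimate; returns (theta_hat, neg_log_post)."""
    from scipy.optimize import minimize

    cells = cells_from_frame(trials) if hasattr(trials, "columns") else trials
    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])

    def f_batch(TH):
        return -log_posterior(spec, TH, cells, config.sigma_nd)

    fg = _value_and_grad(f_batch, lo, hi)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2401]))
    starts = [_data_driven_start(spec, cells)]
    for _ in range(config.n_starts - 1):
        t = lo + rng.uniform(0.05, 0.95, size=spec.n_params) * (hi - lo)
        t[spec.sigma_index] = rng.uniform(3.0, 25.0)
        starts.append(t)
    # keep optimizer iterates strictly inside the prior support
    eps = 1e-6 * (hi - lo)
    opt_bounds = list(zip(lo + eps, hi - eps))
    best, best_val = None, np.inf
    for s in starts:
        res = minimize(fg, np.clip(s, lo + eps, hi - eps), jac=True,
                       method="L-BFGS-B", bounds=opt_bounds,
                       options={"maxiter": 500})
        if res.fun < best_val:
            best, best_val = res.x, float(res.fun)
    return best, best_val


def _hessian_batched(f_batch, x, lo, hi):
    """Central-difference Hessian, evaluated in a single batched call."""
    P = len(x)
    h = np.minimum(1e-3 * (hi - lo), 0.25 * np.minimum(x - lo, hi - x) + 1e-9)
    h = np.maximum(h, 1e-7 * (hi - lo))
    pts = [x]
    for i in range(P):
        for s in (+1, -1):
            p = x.copy(); p[i] += s * h[i]; pts.append(p)
    pairs = [(i, j) for i in range(P) for j in range(i + 1, P)]
    for i, j in pairs:
        for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            p = x.copy(); p[i] += si * h[i]; p[j] += sj * h[j]; pts.append(p)
    vals = f_batch(np.clip(np.array(pts), lo, hi))
    f0 = vals[0]
    H = np.zeros((P, P))
    for i in range(P):
        fp, fm = vals[1 + 2 * i], vals[2 + 2 * i]
        H[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
    k = 1 + 2 * P
    for (i, j) in pairs:
        fpp, fpm, fmp, fmm = vals[k], vals[k + 1], vals[k + 2], vals[k + 3]
        k += 4
        H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def _laplace_draws(spec, theta_hat, cells, config) -> np.ndarray:
    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])
    rng_range = hi - lo
    x = np.clip(theta_hat, lo + 1e-4 * rng_range, hi - 1e-4 * rng_range)

    def f_batch(TH):
        return -log_posterior(spec, TH, cells, config.sigma_nd)

    H = _hessian_batched(f_batch, x, lo, hi)
    # standardize scales before regularizing the curvature
    D = np.diag(rng_range)
    Hs = D @ H @ D
    Hs = 0.5 * (Hs + Hs.T)
    evals, evecs = np.linalg.eigh(Hs)
    evals = np.clip(evals, max(1e-8, 1e-10 * evals.max()), None)
    cov_s = (evecs / evals) @ evecs.T
    cov = D @ cov_s @ D
    from scipy.linalg import solve_triangular

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    P = len(x)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(P) * np.trace(cov))
    # oversample from an inflated multivariate-t, then importance-resample
    # toward the true posterior: corrects the quadratic approximation in flat
    # or skewed directions (weakly identified w, boundary-adjacent rates)
    n_prop = 4 * config.n_laplace_draws
    infl, df = 1.4, 4.0
    z = rng.standard_normal((n_prop, P))
    g = rng.gamma(df / 2.0, 2.0 / df, size=n_prop)
    draws = x[None, :] + infl * (z @ L.T) / np.sqrt(g)[:, None]
    draws = np.clip(draws, lo + 1e-5 * rng_range, hi - 1e-5 * rng_range)
    zc = solve_triangular(infl * L, (draws - x[None, :]).T, lower=True).T
    log_q = -0.5 * (df + P) * np.log1p(np.sum(zc**2, axis=1) / df)
    log_p = log_posterior(spec, draws, cells, config.sigma_nd)
    lw = log_p - log_q
    lw -= lw.max()
    w = np.exp(lw)
    w /= w.sum()
    ess = float(1.0 / np.sum(w**2))
    # systematic resampling keeps the draw count contract exact
    u = (rng.random() + np.arange(config.n_laplace_draws)) / config.n_laplace_draws
    idx = np.searchsorted(np.cumsum(w), u)
    return draws[np.clip(idx, 0, n_prop - 1)], ess


def _diagnostics(draws: np.ndarray, n_chains: int) -> tuple:
    """Split draws into pseudo-chains and compute R-hat / ESS per parameter."""
    import arviz as az

    n, P = draws.shape
    c = max(2, n_chains)
    m = n // c
    arr = draws[: c * m].reshape(c, m, P)
    constant = np.ptp(arr.reshape(-1, P), axis=0) < 1e-12
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ds = az.convert_to_dataset(arr)
        rhat = np.asarray(az.rhat(ds)["x"], dtype=float)
        neff = np.asarray(az.ess(ds)["x"], dtype=float)
    # duplicate draws (importance resampling) can zero a pseudo-chain's
    # variance; report the benign value rather than NaN
    rhat[constant | ~np.isfinite(rhat)] = 1.0
    neff[constant | ~np.isfinite(neff)] = float(n)
    return rhat, neff


# ---------------------------------------------------------------------------
# MCMC route
# ---------------------------------------------------------------------------

def fit_mcmc(spec: ModelSpec, cells, config: FitConfig,
             init: np.ndarray | None = None) -> tuple:
    """Seeded ensemble MCMC; returns (kept draws, walker-chain array)."""
    import emcee

    ndim = spec.n_params
    nwalkers = max(2 * ndim + 2, 2 * config.n_chains)
    nwalkers += nwalkers % 2
    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])

    def log_prob(TH):
        return log_posterior(spec, TH, cells, config.sigma_nd)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1327]))
    center = _data_driven_start(spec, cells) if init is None else np.asarray(init)
    p0 = center[None, :] + 0.05 * (hi - lo) * rng.standard_normal((nwalkers, ndim))
    p0 = np.clip(p0, lo + 1e-4 * (hi - lo), hi - 1e-4 * (hi - lo))

    kept_per_walker = max(1, math.ceil(config.n_kept / nwalkers))
    n_steps = config.n_burnin + kept_per_walker * config.thin
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob, vectorize=True)
    state = emcee.State(p0, random_state=np.random.RandomState(config.seed % (2**31)).get_state())
    sampler.run_mcmc(state, n_steps, progress=False)
    chain = sampler.get_chain(discard=config.n_burnin, thin=config.thin)  # (S, W, P)
    flat = chain.reshape(-1, ndim)
    return flat[: config.n_kept], np.swapaxes(chain, 0, 1)  # (W, S, P)


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def fit_participant(spec_or_id, trials, config: FitConfig = FitConfig(),
                    method: str = "map") -> PosteriorSummary:
    """Fit one model to one participant's trials.

    ``trials`` is a long-format table (or prepared CellData list) holding this
    participant's observed expectation ratings and feedback for one or both
    sessions.  Returns draws, per-draw pointwise log-likelihoods (for LOO),
    posterior means/sds, and convergence diagnostics.  Non-convergence
    (R-hat > 1.05) and degenerate inputs are flagged, never silently dropped.
    """
    from .model_space import get_model

    spec = get_model(spec_or_id) if isinstance(spec_or_id, str) else spec_or_id
    cells = cells_from_frame(trials) if hasattr(trials, "columns") else list(trials)
    flags = []
    obs = np.concatenate([c.observed for c in cells]) if cells else np.array([])
    if len(obs) and np.ptp(obs) < 1e-9:
        flags.append("degenerate_constant_ratings")
    if cells and len({c.session for c in cells}) == 1:
        flags.append("single_session")

    map_est = None
    if method == "map":
        map_est, _ = fit_map(spec, cells, config)
        draws, ess = _laplace_draws(spec, map_est, cells, config)
        if ess < max(50.0, 0.08 * config.n_laplace_draws):
            # the local Gaussian/t proposal missed the posterior mass; refine
            # with a short MAP-initialized ensemble run
            flags.append("laplace_mcmc_refinement")
            short = FitConfig(n_chains=config.n_chains, n_burnin=300,
                              n_kept=config.n_laplace_draws, thin=2,
                              seed=config.seed, sigma_nd=config.sigma_nd)
            draws, _ = fit_mcmc(spec, cells, short, init=map_est)
        chains_for_diag = config.n_chains
    elif method == "mcmc":
        draws, walker_chain = fit_mcmc(spec, cells, config)
        chains_for_diag = walker_chain.shape[0]
    else:
        raise ValueError(f"unknown method {method!r}")

    loglik = pointwise_loglik(spec, draws, cells, config.sigma_nd)
    if method == "mcmc":
        rhat, neff = _diagnostics(draws, chains_for_diag)
    else:
        rhat, neff = _diagnostics(draws, 4)
    if np.any(rhat > 1.05):
        flags.append("nonconvergence")
    summary = PosteriorSummary(
        model_id=spec.model_id,
        method="map_laplace" if method == "map" else "mcmc",
        param_names=spec.param_names,
        mean=draws.mean(axis=0),
        sd=draws.std(axis=0, ddof=1),
        rhat=rhat,
        n_eff=neff,
        draws=draws,
        loglik=loglik,
        flags=flags,
        map_estimate=map_est,
    )
    return summary


def posterior_predictive(spec_or_id, summary: PosteriorSummary, trials):
    """Predicted expectation trajectories from posterior-mean parameters.

    Returns a tidy frame pairing each observed rating with the model's latent
    prediction, plus the participant's R^2 (variance in ratings captured by
    the predictions).
    """
    import pandas as pd

    from .model_space import get_model

    spec = get_model(spec_or_id) if isinstance(spec_or_id, str) else spec_or_id
    cells = cells_from_frame(trials) if hasattr(trials, "columns") else list(trials)
    rows = []
    for c in cells:
        pred = predict_cell(spec, summary.mean, c)[0]
        for t, (o, p) in enumerate(zip(c.observed, pred), start=1):
            rows.append({"session": c.session, "agent": c.agent,
                         "ability": c.ability, "trial": t,
                         "observed": float(o), "predicted": float(p)})
    df = pd.DataFrame(rows)
    resid = df["observed"] - df["predicted"]
    ss_tot = np.sum((df["observed"] - df["observed"].mean()) ** 2)
    r2 = float(1.0 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else np.nan
    return df, r2
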