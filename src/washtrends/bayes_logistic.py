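"""Bayesian regression with a logistic mean and Gaussian errors on the rate scale.

The model for an observed access rate C with normalized covariates X_i and a
0/1 year dummy X_d is

    P   = logistic(intercept + sum_i C_i X_i + C_d X_d)
    C   ~ Normal(P, sigma)

i.e. the mean lives on (0, 1) through the logistic link while the error is
an untruncated Gaussian on the rate scale, so observed rates of exactly 0 or
1 (and improvement outcomes slightly below 0) are valid data.  Priors are
Normal(0, 50) on the intercept and every coefficient, and Normal(0, 50)
truncated to (0, inf) on sigma — practically flat.

Estimation is MCMC: each declared chain is an independent affine-invariant
ensemble (emcee), seeded deterministically; convergence is declared when the
split-chain Gelman–Rubin statistic is below 1.10 for every parameter, and
"significant" means the central 95% credible interval excludes 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import emcee
import numpy as np
import pandas as pd

from .preprocess import AnalysisDataset

_LOG_2PI = math.log(2.0 * math.pi)
RHAT_THRESHOLD = 1.10


@dataclass(frozen=True)
class PriorSpec:
    """Normal(0, sd) priors; sigma's is truncated to the positive half-line."""

    coef_sd: float = 50.0
    sigma_sd: float = 50.0
    sigma_prior: str = "truncated_normal"  # or "flat" (improper, positive)

    def __post_init__(self) -> None:
        if self.coef_sd <= 0 or self.sigma_sd <= 0:
            raise ValueError("prior sds must be positive")
        if self.sigma_prior not in ("truncated_normal", "flat"):
            raise ValueError(f"unknown sigma prior {self.sigma_prior!r}")


@dataclass(frozen=True)
class McmcConfig:
    """Chain geometry: per-chain iterations include the warm-up."""

    iterations: int = 10_000
    chains: int = 4
    warmup: int = 2_000
    seed: int = 0
    walkers: int | None = None  # ensemble size; default max(2*ndim+2, 20)

    def __post_init__(self) -> None:
        if self.iterations <= self.warmup:
            raise ValueError("iterations must exceed warmup")
        if self.chains < 2:
            raise ValueError("need at least 2 chains for R-hat")


@dataclass(frozen=True)
class ModelSpec:
    factor_names: tuple[str, ...]
    include_dummy: bool = True
    prior: PriorSpec = field(default_factory=PriorSpec)
    mcmc: McmcConfig = field(default_factory=McmcConfig)

    def with_seed(self, seed: int) -> "ModelSpec":
        return replace(self, mcmc=replace(self.mcmc, seed=seed))

    @property
    def param_names(self) -> list[str]:
        names = ["intercept", *self.factor_names]
        if self.include_dummy:
            names.append("year_dummy")
        names.append("sigma")
        return names

    @property
    def ndim(self) -> int:
        return len(self.param_names)


@dataclass
class CoefficientVector:
    """One point in parameter space: intercept, per-factor slopes, dummy, sigma."""

    intercept: float
    coefs: np.ndarray
    dummy: float | None
    sigma: float

    def flat(self) -> np.ndarray:
        parts = [self.intercept, *np.atleast_1d(self.coefs)]
        if self.dummy is not None:
            parts.append(self.dummy)
        parts.append(self.sigma)
        return np.asarray(parts, dtype=float)


def logistic(eta):
    """Standard logistic function, overflow-safe for |eta| up to ~1e3."""
    eta = np.asarray(eta, dtype=float)
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out if out.ndim else float(out)


def model_mean(x_row, x_dummy, theta: CoefficientVector) -> float:
    """Logistic of the linear predictor for one observation."""
    x = np.atleast_1d(np.asarray(x_row, dtype=float))
    coefs = np.atleast_1d(np.asarray(theta.coefs, dtype=float))
    if x.shape != coefs.shape:
        raise ValueError(f"covariate length {x.shape} does not match coefficients {coefs.shape}")
    eta = theta.intercept + float(x @ coefs)
    if theta.dummy is not None:
        eta += theta.dummy * float(x_dummy)
    return float(logistic(eta))


def _normal_logpdf(x, sd):
    return -0.5 * _LOG_2PI - math.log(sd) - 0.5 * (np.asarray(x) / sd) ** 2


def log_posterior(theta, data: AnalysisDataset, spec: ModelSpec) -> float:
    """Unnormalized log posterior with all density constants kept.

    ``theta`` may be a :class:`CoefficientVector` or a flat array in
    ``spec.param_names`` order.  Returns ``-inf`` for sigma <= 0.
    """
    vec = theta.flat() if isinstance(theta, CoefficientVector) else np.asarray(theta, float)
    if vec.shape != (spec.ndim,):
        raise ValueError(f"theta length {vec.shape} does not match spec ({spec.ndim} params)")
    design = data.design_matrix(include_dummy=spec.include_dummy)
    return float(_log_prob_batch(vec[None, :], design, data.y, spec)[0])


def _log_prob_batch(thetas: np.ndarray, design: np.ndarray, y: np.ndarray, spec: ModelSpec):
    """Vectorized log posterior over a (walkers, ndim) batch."""
    beta = thetas[:, :-1]
    sigma = thetas[:, -1]
    out = np.full(len(thetas), -np.inf)
    ok = sigma > 0
    if not np.any(ok):
        return out
    b, s = beta[ok], sigma[ok]
    lp = np.sum(_normal_logpdf(b, spec.prior.coef_sd), axis=1)
    if spec.prior.sigma_prior == "truncated_normal":
        lp += math.log(2.0) + _normal_logpdf(s, spec.prior.sigma_sd)
    if len(y):
        p = logistic(design @ b.T)  # (n_rows, n_ok)
        z = (y[:, None] - p) / s[None, :]
        lp += np.sum(-0.5 * _LOG_2PI - 0.5 * z**2, axis=0) - len(y) * np.log(s)
    out[ok] = lp
    return out


def rhat(chains) -> float:
    """Split-chain Gelman–Rubin potential scale reduction factor.

    ``chains`` is (m, n): m parallel sequences of n draws of one parameter.
    Each sequence is split in half (odd trailing draw dropped) before the
    classic between/within variance ratio sqrt(((n−1)/n·W + B/n) / W).
    Returns 1.0 with a warning when every split sequence is constant.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 4:
        raise ValueError("need at least 2 chains of at least 4 draws")
    half = arr.shape[1] // 2
    splits = np.vstack([arr[:, :half], arr[:, half : 2 * half]])
    n = splits.shape[1]
    within = splits.var(axis=1, ddof=1)
    if np.all(within == 0):
        warnings.warn("all split chains constant; R-hat degenerate, returning 1.0", stacklevel=2)
        return 1.0
    w = float(within.mean())
    b = n * float(splits.mean(axis=1).var(ddof=1))
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


@dataclass
class FitResult:
    """Posterior draws plus per-parameter summaries for one model fit.

    ``chain_draws`` is (chains, draws_per_chain, ndim) with draws in step
    order within each chain, so the split-R-hat halves contrast early vs
    late sampling.
    """

    param_names: list[str]
    chain_draws: np.ndarray
    summary: pd.DataFrame
    converged: bool
    n_rows: int
    n_countries_per_year: dict[int, int]
    spec: ModelSpec

    @property
    def draws(self) -> np.ndarray:
        """Post-warmup draws pooled across chains, (total_draws, ndim)."""
        return self.chain_draws.reshape(-1, self.chain_draws.shape[-1])

    def draws_frame(self) -> pd.DataFrame:
        """Pooled draws, one column per parameter, for external diagnostics."""
        return pd.DataFrame(self.draws, columns=self.param_names)

    def parameter(self, name: str) -> pd.Series:
        return self.summary.set_index("parameter").loc[name]


def _initial_walkers(data, spec, nwalkers, rng):
    ndim = spec.ndim
    if data.n_rows == 0:
        # no likelihood: start from the prior, which is the posterior itself
        coefs = rng.normal(0.0, spec.prior.coef_sd, size=(nwalkers, ndim - 1))
        sig = np.abs(rng.normal(0.0, spec.prior.sigma_sd, size=(nwalkers, 1)))
        return np.hstack([coefs, sig])
    design = data.design_matrix(include_dummy=spec.include_dummy)
    yc = np.clip(data.y, 1e-3, 1.0 - 1e-3)
    eta = np.log(yc / (1.0 - yc))
    beta0, *_ = np.linalg.lstsq(design, eta, rcond=None)
    resid_eta = eta - design @ beta0
    dof = max(data.n_rows - design.shape[1], 1)
    s_eta = float(np.sqrt(resid_eta @ resid_eta / dof))
    # spread walkers at the scale of the logit-OLS standard errors so the
    # ensemble starts near-posterior even when the data are near-noiseless
    gram_inv = np.linalg.pinv(design.T @ design)
    se = np.maximum(s_eta * np.sqrt(np.diag(gram_inv)), 1e-4)
    sigma0 = max(float(np.std(data.y - logistic(design @ beta0))), 1e-6)
    p0 = np.empty((nwalkers, ndim))
    p0[:, :-1] = beta0[None, :] + rng.normal(size=(nwalkers, ndim - 1)) * (2.0 * se)[None, :]
    p0[:, -1] = sigma0 * np.abs(1.0 + 0.2 * rng.normal(size=nwalkers))
    return p0


def summarize_draws(chain_draws: np.ndarray, param_names: list[str]) -> pd.DataFrame:
    """Posterior mean, central 95% interval, R-hat and significance per parameter.

    ``chain_draws`` is (chains, draws, ndim); draws are pooled across chains
    for the mean and equal-tailed 2.5/97.5% quantiles, while R-hat is
    computed on the per-chain sequences.  The significance flag is set when
    the 95% interval excludes 0.
    """
    ndim = chain_draws.shape[-1]
    if ndim != len(param_names):
        raise ValueError("param_names length does not match draw dimension")
    pooled = chain_draws.reshape(-1, ndim)
    rows = []
    for j, name in enumerate(param_names):
        lo, hi = np.quantile(pooled[:, j], [0.025, 0.975])
        rows.append(
            {
                "parameter": name,
                "mean": float(pooled[:, j].mean()),
                "cri_low": float(lo),
                "cri_high": float(hi),
                "rhat": rhat(chain_draws[:, :, j]),
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows)


def fit(data: AnalysisDataset, spec: ModelSpec) -> FitResult:
    """Sample the posterior and summarize it.

    Each of ``spec.mcmc.chains`` chains is an independent emcee ensemble;
    per-chain retained draws are at least ``iterations − warmup``.  The run
    is reproducible from ``spec.mcmc.seed``.  Non-convergence (any R-hat ≥
    1.10) warns and returns ``converged=False`` rather than raising.
    """
    if len(spec.factor_names) != (data.X.shape[1] if data.n_rows else len(spec.factor_names)):
        raise ValueError("spec factor count does not match dataset columns")
    ndim = spec.ndim
    mc = spec.mcmc
    nwalkers = mc.walkers or max(2 * ndim + 2, 20)
    keep_steps = max(math.ceil((mc.iterations - mc.warmup) / nwalkers), 2)
    warm_steps = max(math.ceil(mc.warmup / nwalkers), 150)

    design = (
        data.design_matrix(include_dummy=spec.include_dummy)
        if data.n_rows
        else np.empty((0, ndim - 1))
    )
    y = np.asarray(data.y, dtype=float)

    seeds = np.random.SeedSequence(mc.seed).spawn(mc.chains)
    chain_draws = np.empty((mc.chains, keep_steps * nwalkers, ndim))
    for c, ss in enumerate(seeds):
        child = ss.generate_state(2)
        rng = np.random.default_rng(int(child[0]))
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, _log_prob_batch, vectorize=True, args=(design, y, spec)
        )
        sampler.random_state = np.random.RandomState(int(child[1]) % (2**32)).get_state()
        p0 = _initial_walkers(data, spec, nwalkers, rng)
        sampler.run_mcmc(p0, warm_steps + keep_steps, progress=False)
        # (steps, walkers, ndim) -> step-major flat order so split halves are early/late
        chain_draws[c] = sampler.get_chain(discard=warm_steps).reshape(-1, ndim)

    summary = summarize_draws(chain_draws, spec.param_names)
    converged = bool((summary["rhat"] < RHAT_THRESHOLD).all())
    if not converged:
        worst = summary.loc[summary["rhat"].idxmax()]
        warnings.warn(
            f"MCMC not converged: R-hat {worst['rhat']:.3f} for {worst['parameter']}",
            stacklevel=2,
        )
    return FitResult(
        param_names=spec.param_names,
        chain_draws=chain_draws,
        summary=summary,
        converged=converged,
        n_rows=data.n_rows,
        n_countries_per_year=dict(data.n_countries_per_year),
        spec=spec,
    )


def summarize(fit_result: FitResult, decimals: int = 2) -> pd.DataFrame:
    """Per-parameter summary with a display column rounded for reporting.

    Full-precision columns are preserved; ``display`` mirrors the
    "mean (low to high)" convention of published coefficient tables.
    """
    s = fit_result.summary.copy()
    s["display"] = [
        f"{m:.{decimals}f} ({lo:.{decimals}f} to {hi:.{decimals}f})"
        for m, lo, hi in zip(s["mean"], s["cri_low"], s["cri_high"])
    ]
    return s
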