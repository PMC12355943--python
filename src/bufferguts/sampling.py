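"""Bayesian calibration of the survival models.

Posterior sampling uses independent adaptive random-walk Metropolis chains
over log-parameters (all free parameters have positive support).  Each chain
adapts its proposal covariance during warm-up (empirical covariance scaled
by 2.38^2/d, with an acceptance-rate-tuned global factor) and samples with
the proposal frozen.  Independent chains make the stuck-chain filter
meaningful: chains trapped in pseudolocal modes show near-zero parameter
spread and clearly worse mean log-likelihood and are dropped before
posterior summaries are formed.

A multi-start maximum-likelihood mode shares the same likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core import ModelSpec, ParamSet, free_param_names, paramset_from_vector
from .likelihood import LikelihoodEvaluator, SurvivalDataset

__all__ = [
    "LogNormalPrior",
    "LogUniformPrior",
    "SamplerSettings",
    "CalibrationResult",
    "MLEstimate",
    "calibrate",
    "calibrate_ml",
    "filter_chains",
    "default_priors",
]


@dataclass(frozen=True)
class LogNormalPrior:
    """Log-normal prior, parameterized by the median and the log-scale sd."""

    median: float
    sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.median <= 0 or self.sigma <= 0:
            raise ValueError("median and sigma must be > 0")

    def logpdf_logx(self, logx: float) -> float:
        # density of log x (normal), the natural scale for log-space MH
        zscore = (logx - np.log(self.median)) / self.sigma
        return -0.5 * zscore**2 - np.log(self.sigma) - 0.5 * np.log(2 * np.pi)

    def sample_log(self, rng: np.random.Generator) -> float:
        return np.log(self.median) + self.sigma * rng.standard_normal()

    @property
    def log_sd(self) -> float:
        return self.sigma


@dataclass(frozen=True)
class LogUniformPrior:
    """Uniform prior on log x over [low, high]."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError("need 0 < low < high")

    def logpdf_logx(self, logx: float) -> float:
        if np.log(self.low) <= logx <= np.log(self.high):
            return -np.log(np.log(self.high) - np.log(self.low))
        return -np.inf

    def sample_log(self, rng: np.random.Generator) -> float:
        return rng.uniform(np.log(self.low), np.log(self.high))

    @property
    def log_sd(self) -> float:
        return (np.log(self.high) - np.log(self.low)) / np.sqrt(12.0)


Prior = LogNormalPrior | LogUniformPrior


def prior_from_config(cfg: Mapping) -> Prior:
    """Build a prior from a config mapping like
    ``{"dist": "lognormal", "median": 1.0, "sigma": 1.5}``."""
    kind = cfg.get("dist", "lognormal").lower()
    if kind == "lognormal":
        return LogNormalPrior(median=float(cfg["median"]), sigma=float(cfg.get("sigma", 1.5)))
    if kind == "loguniform":
        return LogUniformPrior(low=float(cfg["low"]), high=float(cfg["high"]))
    raise ValueError(f"unknown prior distribution {kind!r}")


def default_priors(
    spec: ModelSpec, include_hb: bool = True, scale: Mapping[str, float] | None = None
) -> dict[str, Prior]:
    """Weakly informative log-normal priors for every free parameter.

    Medians are generic order-of-magnitude guesses (rate constants near
    1/d, weights near the 20 mg food/bee conversion factor, thresholds near
    route-1 exposure scale 0.1); override per parameter via ``scale`` or
    supply your own priors for serious work.
    """
    scale = dict(scale or {})
    defaults = {
        "kd": 1.0, "z": 0.1, "kk": 1.0, "alpha": 0.1, "beta": 3.0, "hb": 0.01,
    }
    priors: dict[str, Prior] = {}
    for name in free_param_names(spec, include_hb=include_hb):
        if name.startswith("kd"):
            med = scale.get(name, defaults["kd"])
        elif name.startswith("w_"):
            med = scale.get(name, 20.0)
        else:
            med = scale.get(name, defaults[name])
        priors[name] = LogNormalPrior(median=med, sigma=1.5)
    return priors


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC settings; defaults follow the standard calibration protocol
    (16 chains, 2000 warm-up + 2000 draw steps)."""

    n_chains: int = 16
    warmup: int = 2000
    draws: int = 2000
    target_accept: float = 0.3
    adapt_start: int = 100  # steps of scale-only adaptation before covariance adaptation

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.warmup < 1 or self.draws < 1:
            raise ValueError("n_chains, warmup and draws must be >= 1")


@dataclass
class CalibrationResult:
    """Per-chain posterior draws and the statistics the chain filter needs."""

    param_names: list[str]
    draws: np.ndarray  # (n_chains, n_draws, n_params), natural scale
    chain_logliks: np.ndarray  # (n_chains, n_draws)
    kept_chains: np.ndarray  # boolean mask
    seed: int | None = None
    settings: SamplerSettings | None = None
    accept_rates: np.ndarray | None = None

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def chain_mean_loglik(self) -> np.ndarray:
        return self.chain_logliks.mean(axis=1)

    @property
    def chain_param_sd(self) -> np.ndarray:
        """(n_chains, n_params) within-chain sample standard deviations."""
        return self.draws.std(axis=1, ddof=1)

    def kept_draws(self) -> np.ndarray:
        """Pooled draws over kept chains, shape (n_kept*n_draws, n_params)."""
        return self.draws[self.kept_chains].reshape(-1, len(self.param_names))

    def quantiles(self, qs: Sequence[float] = (0.025, 0.5, 0.975)) -> pd.DataFrame:
        pooled = self.kept_draws()
        table = np.quantile(pooled, qs, axis=0).T
        return pd.DataFrame(table, index=self.param_names, columns=[f"q{100 * q:g}" for q in qs])

    def summary(self) -> pd.DataFrame:
        q = self.quantiles()
        q.insert(0, "mean", self.kept_draws().mean(axis=0))
        return q

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(draws frame with chain/draw indices, per-chain summary frame)."""
        n_chains, n_draws, _ = self.draws.shape
        idx = pd.MultiIndex.from_product(
            [range(n_chains), range(n_draws)], names=["chain", "draw"]
        )
        draws = pd.DataFrame(
            self.draws.reshape(-1, len(self.param_names)), index=idx, columns=self.param_names
        ).reset_index()
        draws["loglik"] = self.chain_logliks.reshape(-1)
        chains = pd.DataFrame(
            {
                "chain": np.arange(n_chains),
                "mean_loglik": self.chain_mean_loglik,
                "min_param_sd": self.chain_param_sd.min(axis=1),
                "kept": self.kept_chains,
            }
        )
        return draws, chains


def filter_chains(
    result: CalibrationResult,
    sd_min: float = 1e-6,
    worse_factor: float = 1.0,
) -> CalibrationResult:
    """Drop stuck and pseudolocal chains before summarizing the posterior.

    A chain is dropped when any parameter's within-chain standard deviation
    is at or below ``sd_min`` (a frozen sampler), or when its mean
    log-likelihood is more than ``100 * worse_factor`` percent worse than the
    best chain's mean (for the usual negative log-likelihoods this means
    ``mean < best - worse_factor * |best|``).  The best chain is always
    retained.
    """
    mean_ll = result.chain_mean_loglik
    sds = result.chain_param_sd
    best = np.max(mean_ll)
    not_stuck = np.all(sds > sd_min, axis=1)
    good_ll = mean_ll >= best - worse_factor * abs(best)
    kept = not_stuck & good_ll
    if not kept.any():
        kept = np.zeros_like(kept)
        kept[int(np.argmax(mean_ll))] = True
    return replace(result, kept_chains=kept)


def _make_logpost(
    evaluator: LikelihoodEvaluator,
    priors: Mapping[str, Prior],
    names: list[str],
    fixed_hb: float | None,
) -> Callable[[np.ndarray], tuple[float, float]]:
    spec = evaluator.spec

    def logpost(log_theta: np.ndarray) -> tuple[float, float]:
        lp = 0.0
        for name, lx in zip(names, log_theta):
            lp += priors[name].logpdf_logx(lx)
        if not np.isfinite(lp):
            return -np.inf, -np.inf
        theta = np.exp(log_theta)
        if np.any(~np.isfinite(theta)):
            return -np.inf, -np.inf
        try:
            params = paramset_from_vector(spec, theta, hb=fixed_hb)
            ll = evaluator.loglik(params)
        except (ValueError, FloatingPointError):
            return -np.inf, -np.inf
        if not np.isfinite(ll):
            return -np.inf, -np.inf
        return lp + ll, ll

    return logpost


def _run_chain(
    logpost: Callable[[np.ndarray], tuple[float, float]],
    x0: np.ndarray,
    settings: SamplerSettings,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One adaptive-Metropolis chain in log space.

    Returns (draws in log space, per-draw loglik, acceptance rate over the
    sampling phase).
    """
    d = x0.size
    x = x0.copy()
    lp, ll = logpost(x)
    # re-draw a finite starting point if the prior sample is degenerate
    tries = 0
    while not np.isfinite(lp) and tries < 50:
        x = x0 + 0.5 * rng.standard_normal(d)
        lp, ll = logpost(x)
        tries += 1
    if not np.isfinite(lp):
        raise RuntimeError("could not find a finite-posterior starting point")

    scale = 2.38 / np.sqrt(d)
    cov_chol = np.eye(d) * 0.2  # modest initial proposal in log space
    history = np.empty((settings.warmup, d))
    accepted = 0
    window = 0
    for step in range(settings.warmup):
        prop = x + scale * (cov_chol @ rng.standard_normal(d))
        lp_new, ll_new = logpost(prop)
        if np.log(rng.uniform()) < lp_new - lp:
            x, lp, ll = prop, lp_new, ll_new
            accepted += 1
        history[step] = x
        window += 1
        if (step + 1) % 50 == 0:
            rate = accepted / window
            scale *= np.exp(1.5 * (rate - settings.target_accept))
            accepted = 0
            window = 0
            if step + 1 >= settings.adapt_start:
                emp = np.cov(history[: step + 1].T)
                emp = np.atleast_2d(emp) + 1e-8 * np.eye(d)
                try:
                    cov_chol = np.linalg.cholesky(emp)
                except np.linalg.LinAlgError:
                    pass

    draws = np.empty((settings.draws, d))
    logliks = np.empty(settings.draws)
    accepted = 0
    for step in range(settings.draws):
        prop = x + scale * (cov_chol @ rng.standard_normal(d))
        lp_new, ll_new = logpost(prop)
        if np.log(rng.uniform()) < lp_new - lp:
            x, lp, ll = prop, lp_new, ll_new
            accepted += 1
        draws[step] = x
        logliks[step] = ll
    return draws, logliks, accepted / settings.draws


def calibrate(
    spec: ModelSpec,
    dataset: SurvivalDataset,
    priors: Mapping[str, Prior],
    settings: SamplerSettings | None = None,
    seed: int | None = None,
    fixed_hb: float | None = None,
    apply_filter: bool = True,
) -> CalibrationResult:
    """Posterior sampling with independent adaptive Metropolis chains.

    ``fixed_hb`` removes the background hazard from the free parameters and
    pins it (a single shared hb is used across all tests of a calibration).
    Priors must cover every free parameter.
    """
    settings = settings or SamplerSettings()
    names = free_param_names(spec, include_hb=fixed_hb is None)
    missing = [n for n in names if n not in priors]
    if missing:
        raise ValueError(f"missing priors for {missing}")
    evaluator = LikelihoodEvaluator(spec, dataset)
    logpost = _make_logpost(evaluator, priors, names, fixed_hb)

    ss = np.random.SeedSequence(seed if seed is not None else 0)
    child_seeds = ss.spawn(settings.n_chains)
    all_draws = np.empty((settings.n_chains, settings.draws, len(names)))
    all_ll = np.empty((settings.n_chains, settings.draws))
    rates = np.empty(settings.n_chains)
    for c in range(settings.n_chains):
        rng = np.random.default_rng(child_seeds[c])
        x0 = np.array([priors[n].sample_log(rng) for n in names])
        log_draws, logliks, rate = _run_chain(logpost, x0, settings, rng)
        all_draws[c] = np.exp(log_draws)
        all_ll[c] = logliks
        rates[c] = rate
    if np.all(rates < 0.02):
        raise RuntimeError(
            "sampler failed to move in every chain (acceptance < 2%); "
            "check priors and data"
        )
    result = CalibrationResult(
        param_names=list(names),
        draws=all_draws,
        chain_logliks=all_ll,
        kept_chains=np.ones(settings.n_chains, dtype=bool),
        seed=seed,
        settings=settings,
        accept_rates=rates,
    )
    return filter_chains(result) if apply_filter else result


@dataclass
class MLEstimate:
    """Multi-start maximum-likelihood fit sharing the MCMC likelihood."""

    param_names: list[str]
    theta: np.ndarray
    loglik: float
    converged: bool
    n_starts: int

    def paramset(self, spec: ModelSpec, fixed_hb: float | None = None) -> ParamSet:
        return paramset_from_vector(spec, self.theta, hb=fixed_hb)


def calibrate_ml(
    spec: ModelSpec,
    dataset: SurvivalDataset,
    priors: Mapping[str, Prior],
    n_starts: int = 10,
    seed: int | None = None,
    fixed_hb: float | None = None,
) -> MLEstimate:
    """Maximum likelihood by local optimization from ``n_starts`` prior
    draws (priors only provide starting points and bounds here)."""
    names = free_param_names(spec, include_hb=fixed_hb is None)
    evaluator = LikelihoodEvaluator(spec, dataset)

    def negloglik(log_theta: np.ndarray) -> float:
        try:
            params = paramset_from_vector(spec, np.exp(log_theta), hb=fixed_hb)
            ll = evaluator.loglik(params)
        except ValueError:
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        x0 = np.array([priors[n].sample_log(rng) for n in names])
        res = minimize(negloglik, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    return MLEstimate(
        param_names=list(names),
        theta=np.exp(best.x),
        loglik=-float(best.fun),
        converged=bool(best.success),
        n_starts=n_starts,
    )
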