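"""Model/Results facade tying data, likelihood, sampling and selection
together, in the style of statistical modelling packages: build a
:class:`BufferGUTS` model from a dataset, call :meth:`~BufferGUTS.fit`, and
work with the returned :class:`BufferGUTSResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ModelSpec, ParamSet, Trajectory, free_param_names, paramset_from_vector, simulate
from .likelihood import LikelihoodEvaluator, SurvivalDataset
from .sampling import (
    CalibrationResult,
    MLEstimate,
    Prior,
    SamplerSettings,
    calibrate,
    calibrate_ml,
    default_priors,
)
from .selection import VariantMetrics, bic, choose_variant, n_free_parameters, nrmse, pui

__all__ = ["BufferGUTS", "BufferGUTSResults", "compare_variants"]


class BufferGUTS:
    """A multi-route buffered GUTS survival model bound to a dataset.

    Parameters
    ----------
    dataset : SurvivalDataset
        Route-tagged exposure profiles and survivor counts per treatment.
    spec : ModelSpec
        Variant (CA/DA x SD/IT), route count and buffer speed constant.
    priors : mapping, optional
        Prior per free parameter; defaults to weakly informative
        log-normals from :func:`bufferguts.sampling.default_priors`.
    fixed_hb : float, optional
        Pin the background hazard instead of calibrating it.  One shared
        hb applies to all treatments of a calibration either way.
    """

    def __init__(
        self,
        dataset: SurvivalDataset,
        spec: ModelSpec,
        priors: Mapping[str, Prior] | None = None,
        fixed_hb: float | None = None,
    ):
        self.dataset = dataset
        self.spec = spec
        self.fixed_hb = fixed_hb
        self.priors = dict(
            priors
            if priors is not None
            else default_priors(spec, include_hb=fixed_hb is None)
        )
        self.param_names = free_param_names(spec, include_hb=fixed_hb is None)
        self._evaluator = LikelihoodEvaluator(spec, dataset)

    @classmethod
    def from_frames(
        cls,
        exposure: pd.DataFrame,
        survival: pd.DataFrame,
        spec: ModelSpec,
        **kwargs,
    ) -> "BufferGUTS":
        dataset = SurvivalDataset.from_frames(exposure, survival, spec.n_routes)
        return cls(dataset, spec, **kwargs)

    @property
    def k_free(self) -> int:
        """Free-parameter count entering the BIC."""
        return n_free_parameters(
            self.spec.combination,
            self.spec.death,
            self.spec.n_routes,
            include_hb=self.fixed_hb is None,
        )

    def loglike(self, params: ParamSet) -> float:
        return self._evaluator.loglik(params)

    def fit(
        self,
        method: str = "mcmc",
        settings: SamplerSettings | None = None,
        seed: int | None = None,
        apply_filter: bool = True,
        n_starts: int = 10,
    ) -> "BufferGUTSResults":
        """Calibrate the model; ``method`` is ``"mcmc"`` or ``"ml"``."""
        if method == "mcmc":
            calibration = calibrate(
                self.spec,
                self.dataset,
                self.priors,
                settings=settings,
                seed=seed,
                fixed_hb=self.fixed_hb,
                apply_filter=apply_filter,
            )
            return BufferGUTSResults(self, calibration=calibration)
        if method == "ml":
            ml = calibrate_ml(
                self.spec,
                self.dataset,
                self.priors,
                n_starts=n_starts,
                seed=seed,
                fixed_hb=self.fixed_hb,
            )
            return BufferGUTSResults(self, ml=ml)
        raise ValueError(f"unknown method {method!r}; use 'mcmc' or 'ml'")


class BufferGUTSResults:
    """Fit results: point estimates, uncertainty, diagnostics, prediction."""

    def __init__(
        self,
        model: BufferGUTS,
        calibration: CalibrationResult | None = None,
        ml: MLEstimate | None = None,
    ):
        if (calibration is None) == (ml is None):
            raise ValueError("provide exactly one of calibration or ml")
        self.model = model
        self.calibration = calibration
        self.ml = ml

    @property
    def method(self) -> str:
        return "mcmc" if self.calibration is not None else "ml"

    @property
    def param_names(self) -> list[str]:
        return list(self.model.param_names)

    @property
    def theta(self) -> np.ndarray:
        """Point estimate: posterior median over kept chains, or the MLE."""
        if self.ml is not None:
            return self.ml.theta
        return np.median(self.calibration.kept_draws(), axis=0)

    @property
    def params(self) -> ParamSet:
        return paramset_from_vector(self.model.spec, self.theta, hb=self.model.fixed_hb)

    @property
    def llf(self) -> float:
        """Log-likelihood at the point estimate."""
        if self.ml is not None:
            return self.ml.loglik
        return self.model.loglike(self.params)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        if self.calibration is None:
            raise ValueError("credible intervals require an MCMC fit")
        return self.calibration.quantiles((alpha / 2, 0.5, 1 - alpha / 2))

    def bic(self) -> float:
        return bic(self.llf, self.model.k_free, self.model.dataset.n_observations)

    def predicted_counts(self, dataset: SurvivalDataset | None = None, params: ParamSet | None = None) -> np.ndarray:
        ev = (
            self.model._evaluator
            if dataset is None
            else LikelihoodEvaluator(self.model.spec, dataset)
        )
        return ev.predicted_counts(params if params is not None else self.params)

    def nrmse(
        self, dataset: SurvivalDataset | None = None, with_interval: bool = False,
        n_draws: int = 200, seed: int = 0,
    ) -> float | tuple[float, tuple[float, float]]:
        """NRMSE of predicted vs observed survivor counts (fraction).

        With ``with_interval`` (MCMC only) also returns the 95% interval of
        the NRMSE over a posterior-parameter subsample.
        """
        ds = dataset if dataset is not None else self.model.dataset
        observed = ds.observed_counts()
        point = nrmse(observed, self.predicted_counts(dataset))
        if not with_interval:
            return point
        if self.calibration is None:
            raise ValueError("NRMSE intervals require an MCMC fit")
        pooled = self.calibration.kept_draws()
        rng = np.random.default_rng(seed)
        take = rng.choice(len(pooled), size=min(n_draws, len(pooled)), replace=False)
        vals = []
        for row in pooled[take]:
            p = paramset_from_vector(self.model.spec, row, hb=self.model.fixed_hb)
            vals.append(nrmse(observed, self.predicted_counts(dataset, params=p)))
        lo, hi = np.quantile(vals, [0.025, 0.975])
        return point, (float(lo), float(hi))

    def pui(self) -> float:
        """Parameter uncertainty index over the non-background parameters."""
        if self.calibration is None:
            raise ValueError("PUI requires an MCMC fit")
        q = self.calibration.quantiles()
        q = q.drop(index="hb", errors="ignore")
        return pui(q)

    def metrics(self, dataset_id: str = "default") -> VariantMetrics:
        point, interval = self.nrmse(with_interval=True) if self.calibration else (self.nrmse(), None)
        return VariantMetrics(
            variant=self.model.spec.variant,
            k=self.model.k_free,
            n=self.model.dataset.n_observations,
            bic=self.bic(),
            nrmse=point,
            pui=self.pui() if self.calibration else 0.0,
            dataset_id=dataset_id,
            nrmse_interval=interval,
        )

    def predict(self, profiles, times) -> Trajectory:
        """Simulate the fitted model for a new exposure scenario."""
        return simulate(self.model.spec, self.params, profiles, times)

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Buffered GUTS survival model results",
            "=" * 52,
            f"Variant:        {spec.variant}  (routes: {spec.n_routes}, eta={spec.eta}/d)",
            f"Method:         {self.method}",
            f"Treatments:     {len(self.model.dataset.treatments)}",
            f"Observations:   {self.model.dataset.n_observations}",
            f"Free params k:  {self.model.k_free}"
            + ("" if self.model.fixed_hb is None else f"  (hb fixed at {self.model.fixed_hb})"),
            f"Log-likelihood: {self.llf:.3f}",
            f"BIC:            {self.bic():.3f}",
            f"NRMSE:          {100 * self.nrmse():.2f}%",
        ]
        if self.calibration is not None:
            kept = int(self.calibration.kept_chains.sum())
            lines.append(
                f"Chains kept:    {kept}/{self.calibration.n_chains}"
            )
            lines.append(f"PUI:            {self.pui():.3f}")
            lines.append("")
            table = self.calibration.summary().round(5)
            lines.append(table.to_string())
        else:
            lines.append("")
            est = pd.Series(self.theta, index=self.param_names, name="estimate")
            lines.append(est.round(6).to_string())
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed survival fractions vs fitted curves, one line per
        treatment (matplotlib imported lazily)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ev = self.model._evaluator
        for tr, traj in zip(self.model.dataset.treatments, ev.survival_curves(self.params)):
            (line,) = ax.plot(traj.times, traj.S, lw=1)
            ax.plot(
                tr.times,
                np.asarray(tr.n_alive) / tr.n_start,
                "o",
                ms=3,
                color=line.get_color(),
            )
        ax.set_xlabel("time [d]")
        ax.set_ylabel("survival")
        ax.set_ylim(-0.02, 1.02)
        return ax


def compare_variants(
    dataset: SurvivalDataset,
    n_routes: int,
    eta: float = 2.0,
    variants: Sequence[tuple[str, str]] = (("CA", "SD"), ("CA", "IT"), ("DA", "SD"), ("DA", "IT")),
    priors: Mapping[str, Mapping[str, Prior]] | None = None,
    settings: SamplerSettings | None = None,
    seed: int | None = None,
    fixed_hb: float | None = None,
    dataset_id: str = "default",
) -> tuple[VariantMetrics, list[str], list["BufferGUTSResults"]]:
    """Fit all four variants to one dataset and apply the choice rule.

    Returns the chosen variant's metrics, the rationale trail, and the
    fitted results in variant order.
    """
    results = []
    metrics = []
    for combination, death in variants:
        spec = ModelSpec(combination=combination, death=death, n_routes=n_routes, eta=eta)
        var_priors = priors.get(spec.variant) if priors else None
        model = BufferGUTS(dataset, spec, priors=var_priors, fixed_hb=fixed_hb)
        res = model.fit(settings=settings, seed=seed)
        results.append(res)
        metrics.append(res.metrics(dataset_id=dataset_id))
    winner, rationale = choose_variant(metrics)
    return winner, rationale, results
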