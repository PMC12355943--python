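"""Multinomial survival likelihood over interval-censored death counts.

Each treatment follows a cohort of ``n_start`` individuals; the numbers
dying within each observation interval and the number surviving the final
observation are jointly multinomial with cell probabilities given by the
model survival curve:

    p_j = S(t_{j-1}) - S(t_j)   (death in interval j),
    p_surv = S(t_J)             (alive at the last observation).

The log-likelihood is the multinomial kernel (without the combinatorial
coefficient, which is parameter-independent and drops out of all
inference); it equals the multinomial log-pmf up to that constant, and is
exactly additive over replicate batches, so summing replicates leaves it
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ExposureProfile, ModelSpec, ParamSet, Trajectory, default_grid, simulate

PROB_FLOOR = 1e-12

__all__ = ["Treatment", "SurvivalDataset", "LikelihoodEvaluator", "log_likelihood"]


@dataclass(frozen=True)
class Treatment:
    """Observed survival of one (summed) treatment with its exposures."""

    test_id: str
    treatment_id: str
    profiles: tuple[ExposureProfile, ...]
    times: tuple[float, ...]  # observation times in days, starting at 0
    n_alive: tuple[int, ...]
    design: str | None = None

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        n = tuple(int(x) for x in self.n_alive)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "n_alive", n)
        object.__setattr__(self, "profiles", tuple(self.profiles))
        if len(times) != len(n) or len(times) < 2:
            raise ValueError("need matching times/counts with at least two points")
        if times[0] != 0.0:
            raise ValueError("observations must start at t = 0")
        if any(b <= a for a, b in zip(times[:-1], times[1:])):
            raise ValueError("observation times must be strictly increasing")
        if any(b > a for a, b in zip(n[:-1], n[1:])):
            raise ValueError(
                f"survivor counts increase in {self.test_id}/{self.treatment_id}"
            )

    @property
    def n_start(self) -> int:
        return self.n_alive[0]


@dataclass
class SurvivalDataset:
    """Collection of treatments sharing one route convention."""

    treatments: list[Treatment]
    n_routes: int

    def __post_init__(self) -> None:
        for tr in self.treatments:
            if len(tr.profiles) != self.n_routes:
                raise ValueError(
                    f"treatment {tr.test_id}/{tr.treatment_id} has "
                    f"{len(tr.profiles)} profiles, expected {self.n_routes}"
                )

    @property
    def n_observations(self) -> int:
        """Observation count used as n in the BIC: post-t0 survival records
        summed over treatments (the t=0 baseline is not a random outcome)."""
        return sum(len(tr.times) - 1 for tr in self.treatments)

    def subset(self, designs: Sequence[str]) -> "SurvivalDataset":
        keep = [tr for tr in self.treatments if tr.design in set(designs)]
        if not keep:
            raise ValueError(f"no treatments with design in {sorted(set(designs))}")
        return SurvivalDataset(keep, self.n_routes)

    def observed_counts(self) -> np.ndarray:
        """All post-t0 survivor counts, flattened in treatment order."""
        return np.concatenate([np.asarray(tr.n_alive[1:], dtype=float) for tr in self.treatments])

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(exposure frame, survival frame) in the package CSV schema."""
        exp_rows, surv_rows = [], []
        for tr in self.treatments:
            for p in tr.profiles:
                for t0, t1, level in p.segments:
                    exp_rows.append(
                        (tr.test_id, tr.treatment_id, p.route_id, p.unit, t0, t1, level)
                    )
                if not p.segments:
                    exp_rows.append((tr.test_id, tr.treatment_id, p.route_id, p.unit, 0.0, 0.0, 0.0))
            for t, n in zip(tr.times, tr.n_alive):
                surv_rows.append((tr.test_id, tr.treatment_id, t, n, tr.design))
        exposure = pd.DataFrame(
            exp_rows,
            columns=["test_id", "treatment_id", "route_id", "unit", "t_start_d", "t_end_d", "level"],
        )
        survival = pd.DataFrame(
            surv_rows, columns=["test_id", "treatment_id", "time_d", "n_alive", "design"]
        )
        return exposure, survival

    @classmethod
    def from_frames(
        cls, exposure: pd.DataFrame, survival: pd.DataFrame, n_routes: int
    ) -> "SurvivalDataset":
        treatments = []
        for (test_id, treatment_id), surv in survival.groupby(
            ["test_id", "treatment_id"], sort=False
        ):
            surv = surv.sort_values("time_d")
            exp = exposure[
                (exposure["test_id"] == test_id)
                & (exposure["treatment_id"] == treatment_id)
            ]
            profiles = []
            for route in range(1, n_routes + 1):
                seg_rows = exp[exp["route_id"] == route]
                if seg_rows.empty:
                    raise ValueError(
                        f"missing route {route} exposure for {test_id}/{treatment_id}"
                    )
                segs = tuple(
                    (float(r.t_start_d), float(r.t_end_d), float(r.level))
                    for r in seg_rows.sort_values("t_start_d").itertuples()
                    if r.t_end_d > r.t_start_d
                )
                profiles.append(
                    ExposureProfile(
                        route_id=route, unit=str(seg_rows["unit"].iloc[0]), segments=segs
                    )
                )
            design = surv["design"].iloc[0] if "design" in surv.columns else None
            treatments.append(
                Treatment(
                    test_id=str(test_id),
                    treatment_id=str(treatment_id),
                    profiles=tuple(profiles),
                    times=tuple(surv["time_d"]),
                    n_alive=tuple(surv["n_alive"]),
                    design=None if pd.isna(design) else design,
                )
            )
        return cls(treatments, n_routes)


def _treatment_loglik(S_obs: np.ndarray, n_alive: np.ndarray) -> float:
    deaths = -np.diff(n_alive)
    p_int = np.maximum(-np.diff(S_obs), PROB_FLOOR)
    p_surv = max(S_obs[-1], PROB_FLOOR)
    n_final = n_alive[-1]
    return float(deaths @ np.log(p_int) + n_final * np.log(p_surv))


class LikelihoodEvaluator:
    """Caches per-treatment evaluation grids for fast repeated evaluation.

    The simulation grid per treatment is the union of exposure breakpoints,
    observation times and an hourly grid, so the piecewise-linear hazard
    integration of the SD mechanism is resolved at the exposure
    discretization scale.
    """

    def __init__(self, spec: ModelSpec, dataset: SurvivalDataset, resolution: float | None = None):
        if dataset.n_routes != spec.n_routes:
            raise ValueError(
                f"dataset has {dataset.n_routes} routes, spec expects {spec.n_routes}"
            )
        from .core import HOUR

        self.spec = spec
        self.dataset = dataset
        self._grids: list[np.ndarray] = []
        self._obs_idx: list[np.ndarray] = []
        res = HOUR if resolution is None else resolution
        for tr in dataset.treatments:
            grid = default_grid(tr.profiles, obs_times=tr.times, horizon=tr.times[-1], resolution=res)
            idx = np.searchsorted(grid, np.asarray(tr.times))
            if np.any(np.abs(grid[idx] - np.asarray(tr.times)) > 1e-9):
                raise ValueError("observation times missing from evaluation grid")
            self._grids.append(grid)
            self._obs_idx.append(idx)

    def survival_curves(self, params: ParamSet) -> list[Trajectory]:
        return [
            simulate(self.spec, params, tr.profiles, grid)
            for tr, grid in zip(self.dataset.treatments, self._grids)
        ]

    def predicted_survival(self, params: ParamSet) -> list[np.ndarray]:
        """Model survival probability at each treatment's observation times."""
        out = []
        for tr, grid, idx in zip(self.dataset.treatments, self._grids, self._obs_idx):
            traj = simulate(self.spec, params, tr.profiles, grid)
            out.append(traj.S[idx])
        return out

    def predicted_counts(self, params: ParamSet) -> np.ndarray:
        """Expected survivor counts at all post-t0 observation points."""
        preds = []
        for tr, S in zip(self.dataset.treatments, self.predicted_survival(params)):
            preds.append(tr.n_start * S[1:])
        return np.concatenate(preds)

    def loglik(self, params: ParamSet) -> float:
        total = 0.0
        for tr, S in zip(self.dataset.treatments, self.predicted_survival(params)):
            total += _treatment_loglik(S, np.asarray(tr.n_alive))
        return total


def log_likelihood(spec: ModelSpec, params: ParamSet, dataset: SurvivalDataset) -> float:
    """Multinomial survival log-likelihood of ``params`` for ``dataset``."""
    return LikelihoodEvaluator(spec, dataset).loglik(params)
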