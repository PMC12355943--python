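"""Synthetic honeybee-style survival studies generated from known parameters.

Emulates the three standard regulatory designs — acute contact (single 1-h
topical pulse, 2-day observation), acute oral (6-h feeding, 2-day
observation) and chronic oral (constant dietary exposure over 10 days) —
with batches of ten bees and daily survival observations.  Death counts per
observation interval are drawn by sequential conditional binomials from the
model survival curve, so the generated data follow the exact sampling model
the likelihood assumes.  What the generator does not emulate: food
avoidance, consumption decline at high concentrations, between-batch
heterogeneity, or observation-time jitter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ExposureProfile, ModelSpec, ParamSet, default_grid, simulate
from .exposure import CONTACT_UNIT, FOOD_UNIT, TestRecord, discretize
from .likelihood import SurvivalDataset, Treatment

__all__ = [
    "DesignTemplate",
    "Scenario",
    "default_true_params",
    "generate",
    "default_templates",
    "find_level_for_mortality",
    "make_validation_suite",
]


def default_true_params(spec: ModelSpec) -> ParamSet:
    """Honeybee-plausible generating parameters for synthetic studies.

    Contact (route 1) is anchored in ug a.i./bee; the oral weight 0.02
    (ug a.i./bee per mg a.i./kg food) is the equal-potency value implied by
    20 mg food consumed per bee, i.e. ingested and topical amounts are
    equally toxic.  Rate constants are in the range where acute mortality
    develops over the first days.  Background mortality defaults to zero so
    that synthetic studies isolate the substance effect; pass your own
    :class:`~bufferguts.core.ParamSet` for non-zero control mortality.
    """
    n_kd = 1 if spec.combination == "CA" else spec.n_routes
    kd = tuple([0.7, 1.2, 0.9, 0.8][:n_kd])
    w = (1.0,) + (0.02,) * (spec.n_routes - 1)
    if spec.death == "SD":
        return ParamSet(kd=kd, w=w, z=0.002, kk=400.0, hb=0.0)
    return ParamSet(kd=kd, w=w, alpha=0.004, beta=2.5, hb=0.0)

#: observation schedule per design: (test duration in days, daily grid)
_DESIGN_DEFAULTS = {
    "acute_contact": 2.0,
    "acute_oral": 2.0,
    "chronic_oral": 10.0,
}


@dataclass(frozen=True)
class DesignTemplate:
    """One test design with its concentration ladder.

    ``levels`` are in the design's native unit (ug a.i./bee for acute
    designs, mg a.i./kg food for chronic oral) and must include a control
    (0).  Individuals per treatment default to 4 batches of 10 bees.
    """

    design: str
    levels: tuple[float, ...]
    n_batches: int = 4
    batch_size: int = 10
    obs_times: tuple[float, ...] | None = None
    feeding_duration_h: float = 6.0

    def __post_init__(self) -> None:
        if self.design not in _DESIGN_DEFAULTS:
            raise ValueError(f"unknown design {self.design!r}")
        levels = tuple(float(x) for x in self.levels)
        object.__setattr__(self, "levels", levels)
        if any(x < 0 for x in levels):
            raise ValueError("levels must be >= 0")
        if 0.0 not in levels:
            raise ValueError("levels must include a control (0)")
        duration = _DESIGN_DEFAULTS[self.design]
        if self.obs_times is None:
            object.__setattr__(
                self, "obs_times", tuple(np.arange(0.0, duration + 0.5, 1.0))
            )
        obs = self.obs_times
        if obs[0] != 0.0 or obs[-1] < duration - 1e-9:
            raise ValueError("observation grid must include t=0 and the test end")

    @property
    def duration_d(self) -> float:
        return self.obs_times[-1]

    @property
    def n_per_treatment(self) -> int:
        return self.n_batches * self.batch_size


def _route_profiles(
    spec: ModelSpec, template: DesignTemplate, level: float
) -> tuple[ExposureProfile, ...]:
    """Route-tagged profiles for one treatment (zero on the unused route)."""
    record = TestRecord(
        compound="synthetic",
        report_no="synthetic",
        design=template.design,
        dose_or_conc=level,
        test_duration_d=template.duration_d,
        n_start=template.n_per_treatment,
        feeding_duration_h=template.feeding_duration_h,
    )
    if template.design == "acute_contact":
        active = discretize(record, route_id=1)
        route = 1
    else:
        active = discretize(record, route_id=2)
        route = 2
    if spec.n_routes == 1:
        return (active,)
    if spec.n_routes != 2:
        raise ValueError("templates cover the two-route contact+oral convention")
    other_unit = FOOD_UNIT if route == 1 else CONTACT_UNIT
    silent = ExposureProfile(route_id=3 - route, unit=other_unit, segments=())
    if route == 1:
        return (active, silent)
    return (silent, active)


def generate(
    spec: ModelSpec,
    true_params: ParamSet,
    templates: Sequence[DesignTemplate],
    seed: int | None = None,
) -> SurvivalDataset:
    """Draw one synthetic study from known parameters.

    Per treatment the survivor counts follow sequential conditional
    binomials, ``n_j ~ Binomial(n_{j-1}, S(t_j)/S(t_{j-1}))``; controls
    experience only the background hazard.  Identical seeds give identical
    datasets.
    """
    rng = np.random.default_rng(seed)
    treatments = []
    for ti, template in enumerate(templates):
        for li, level in enumerate(template.levels):
            profiles = _route_profiles(spec, template, level)
            grid = default_grid(
                profiles, obs_times=template.obs_times, horizon=template.duration_d
            )
            traj = simulate(spec, true_params, profiles, grid)
            S = traj.survival_at(np.asarray(template.obs_times))
            n = template.n_per_treatment
            counts = [n]
            for j in range(1, len(S)):
                p = 1.0 if S[j - 1] <= 0 else min(1.0, S[j] / S[j - 1])
                n = rng.binomial(n, p)
                counts.append(int(n))
            treatments.append(
                Treatment(
                    test_id=f"{template.design}_{ti}",
                    treatment_id=f"L{li}",
                    profiles=profiles,
                    times=template.obs_times,
                    n_alive=tuple(counts),
                    design=template.design,
                )
            )
    return SurvivalDataset(treatments, spec.n_routes)


def find_level_for_mortality(
    spec: ModelSpec,
    params: ParamSet,
    design: str,
    target_survival: float = 0.5,
    feeding_duration_h: float = 6.0,
) -> float:
    """Exposure level whose end-of-test survival equals ``target_survival``
    under ``params`` (substance effect only, background hazard off).

    Bisection on the level; this is the model-implied LD50/LC50 when the
    target is 0.5.
    """
    params_nobg = ParamSet(
        kd=params.kd, w=params.w, z=params.z, kk=params.kk,
        alpha=params.alpha, beta=params.beta, hb=0.0,
    )
    template = DesignTemplate(
        design=design, levels=(0.0, 1.0), feeding_duration_h=feeding_duration_h
    )

    def end_survival(level: float) -> float:
        profiles = _route_profiles(spec, template, level)
        grid = default_grid(profiles, obs_times=template.obs_times, horizon=template.duration_d)
        traj = simulate(spec, params_nobg, profiles, grid)
        return float(traj.S[-1])

    lo, hi = 0.0, 1.0
    for _ in range(200):
        if end_survival(hi) < target_survival:
            break
        hi *= 4.0
    else:
        raise RuntimeError("could not bracket the target mortality level")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if end_survival(mid) > target_survival:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def default_templates(
    spec: ModelSpec, params: ParamSet, n_batches: int = 4
) -> list[DesignTemplate]:
    """The standard miniature study: 3 designs x (control + 5 levels).

    Ladders are geometric with factor 2 around the level giving ~50%
    end-of-test mortality under the true parameters, mirroring regulatory
    dose-ranging practice.
    """
    templates = []
    for design in ("acute_contact", "acute_oral", "chronic_oral"):
        mid = find_level_for_mortality(spec, params, design)
        ladder = tuple(mid * f for f in (0.25, 0.5, 1.0, 2.0, 4.0))
        templates.append(
            DesignTemplate(design=design, levels=(0.0,) + ladder, n_batches=n_batches)
        )
    return templates


@dataclass(frozen=True)
class Scenario:
    """One combined contact+oral validation scenario."""

    contact_dose: float  # ug a.i./bee, 1-h pulse at t=0
    oral_level: float  # mg a.i./kg food
    oral_start: float  # days after the contact pulse
    oral_duration: float  # days
    horizon: float  # days


def make_validation_suite(
    contact_dose: float = 0.12,
    oral_level: float = 20.0,
    oral_durations: Sequence[float] = (1.0, 2.0),
    delays: Sequence[float] = (0.0, 1.0, 2.0, 4.0, 7.0),
    tail_d: float = 3.0,
) -> list[Scenario]:
    """Grid of proposed validation scenarios: a contact pulse at t=0 crossed
    with oral exposure windows of 1 and 2 days at varying inter-peak delays.

    Oral durations of 1-2 days deliberately differ from the calibration
    designs (6-h acute, 10-d chronic), so they probe unseen exposure
    patterns.  The default exposure levels follow the worked pyrethroid
    example (0.12 ug a.i./bee contact, 20 mg a.i./kg food oral).
    """
    scenarios = []
    for duration in oral_durations:
        for delay in delays:
            scenarios.append(
                Scenario(
                    contact_dose=contact_dose,
                    oral_level=oral_level,
                    oral_start=delay,
                    oral_duration=duration,
                    horizon=delay + duration + tail_d,
                )
            )
    return scenarios
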