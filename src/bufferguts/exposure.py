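"""Conversion of standard regulatory test designs into exposure profiles.

Covers the three honeybee laboratory designs — acute contact (1-h topical
pulse), acute oral (single feeding of up to 6 h), chronic oral (constant
dietary exposure over the whole test, typically 10 d) — plus the data-hygiene
steps applied before calibration: replicate summation and the exclusion of
acute-oral tests whose 48-h LD50 is wildly inconsistent with the other tests
of the same compound.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import HOUR, ExposureProfile

DESIGNS = ("acute_contact", "acute_oral", "chronic_oral")
CONTACT_UNIT = "ug a.i./bee"
FOOD_UNIT = "mg a.i./kg food"

#: default food consumption assumed during the acute-oral feeding phase
DEFAULT_CONSUMPTION_MG = 20.0

__all__ = [
    "TestRecord",
    "DESIGNS",
    "CONTACT_UNIT",
    "FOOD_UNIT",
    "DEFAULT_CONSUMPTION_MG",
    "convert_acute_oral_dose",
    "invert_acute_oral_conc",
    "discretize",
    "sum_replicates",
    "exclude_outlier_tests",
    "read_profiles_csv",
    "write_profiles_csv",
]


@dataclass(frozen=True)
class TestRecord:
    """One treatment of one regulatory test, with its survival observations."""

    compound: str
    report_no: str
    design: str
    dose_or_conc: float
    test_duration_d: float
    n_start: int
    observations: tuple[tuple[float, int], ...] = ()
    feeding_duration_h: float = 6.0  # acute oral only
    unit: str | None = None

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; expected one of {DESIGNS}")
        if self.dose_or_conc < 0:
            raise ValueError("dose_or_conc must be >= 0")
        obs = tuple((float(t), int(n)) for t, n in self.observations)
        object.__setattr__(self, "observations", obs)
        if obs:
            if obs[0][0] != 0.0 or obs[0][1] != self.n_start:
                raise ValueError("observations must start at (0, n_start)")
            counts = [n for _, n in obs]
            if any(b > a for a, b in zip(counts[:-1], counts[1:])):
                raise ValueError("survivor counts must be non-increasing")


def convert_acute_oral_dose(
    dose_ug_per_bee: float, consumption_mg_per_bee: float = DEFAULT_CONSUMPTION_MG
) -> float:
    """Convert an acute-oral dose (ug a.i./bee) into the concentration of the
    consumed food solution (mg a.i./kg food).

    The whole dose is assumed to be ingested with ``consumption_mg_per_bee``
    milligrams of food, so the food concentration is ``dose / consumption``
    in ug/mg, which equals ``dose / consumption * 1000`` in mg/kg.
    """
    if consumption_mg_per_bee <= 0:
        raise ValueError("consumption must be > 0")
    if dose_ug_per_bee < 0:
        raise ValueError("dose must be >= 0")
    return dose_ug_per_bee / consumption_mg_per_bee * 1000.0


def invert_acute_oral_conc(
    conc_mg_per_kg: float, consumption_mg_per_bee: float = DEFAULT_CONSUMPTION_MG
) -> float:
    """Inverse of :func:`convert_acute_oral_dose` (mg/kg food -> ug/bee)."""
    if consumption_mg_per_bee <= 0:
        raise ValueError("consumption must be > 0")
    return conc_mg_per_kg * consumption_mg_per_bee / 1000.0


def discretize(
    record: TestRecord,
    route_id: int = 1,
    consumption_mg_per_bee: float = DEFAULT_CONSUMPTION_MG,
) -> ExposureProfile:
    """Turn a test-design descriptor into a piecewise-constant profile.

    The smallest exposure time unit is 1 h: instantaneous applications
    (topical contact doses) are modelled as a constant 1-h pulse so that
    their area under the curve equals one dose-hour.
    """
    d = record.design
    if d == "acute_contact":
        return ExposureProfile(
            route_id=route_id,
            unit=CONTACT_UNIT,
            segments=((0.0, HOUR, record.dose_or_conc),),
        )
    if d == "acute_oral":
        fh = record.feeding_duration_h
        if fh <= 0 or fh > 6.0:
            raise ValueError(
                f"acute-oral feeding duration must be in (0, 6] h, got {fh}"
            )
        level = convert_acute_oral_dose(record.dose_or_conc, consumption_mg_per_bee)
        return ExposureProfile(
            route_id=route_id,
            unit=FOOD_UNIT,
            segments=((0.0, fh * HOUR, level),),
        )
    # chronic oral: constant over the whole test despite daily replenishment
    if record.unit is not None and record.unit != FOOD_UNIT:
        raise ValueError(
            f"chronic oral exposure must be given in {FOOD_UNIT!r}, got {record.unit!r}"
        )
    return ExposureProfile(
        route_id=route_id,
        unit=FOOD_UNIT,
        segments=((0.0, record.test_duration_d, record.dose_or_conc),),
    )


def sum_replicates(records: Sequence[TestRecord]) -> TestRecord:
    """Sum survivor counts of replicate batches of one treatment.

    All replicates must share the observation grid.  The summed record gives
    the same likelihood as the per-replicate product up to a
    parameter-independent combinatorial constant, so inference is unchanged.
    """
    if not records:
        raise ValueError("no records to sum")
    first = records[0]
    times = [t for t, _ in first.observations]
    for r in records[1:]:
        if [t for t, _ in r.observations] != times:
            raise ValueError(
                f"observation times of replicate {r.report_no!r} do not match"
            )
        if (r.compound, r.design, r.dose_or_conc) != (
            first.compound,
            first.design,
            first.dose_or_conc,
        ):
            raise ValueError("replicates must belong to the same treatment")
    counts = np.sum([[n for _, n in r.observations] for r in records], axis=0)
    return replace(
        first,
        n_start=int(sum(r.n_start for r in records)),
        observations=tuple(zip(times, (int(c) for c in counts))),
    )


def exclude_outlier_tests(
    tests: pd.DataFrame,
    factor: float = 8.0,
    require_all_others: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag inconsistent acute-oral tests.

    An acute-oral test is excluded iff its 48-h LD50 differs by at least
    ``factor`` from the 48-h LD50 of every other acute-oral test of the same
    compound (``require_all_others=False`` relaxes this to *any* other test)
    AND its 48-h food-concentration LC50 is lower than the compound's chronic
    10-day LC50.  Both conditions guard against dropping tests that merely
    disagree with each other.

    ``tests`` needs columns ``compound, report_no, design, ld50_48h_ug_bee,
    lc50_48h_or_10d_mg_kg``; chronic rows carry the 10-day LC50 in the latter
    column.  Returns ``(kept, excluded)`` frames covering *all* designs.
    """
    required = {"compound", "report_no", "design", "ld50_48h_ug_bee", "lc50_48h_or_10d_mg_kg"}
    missing = required - set(tests.columns)
    if missing:
        raise ValueError(f"tests table lacks columns {sorted(missing)}")
    flags = pd.Series(False, index=tests.index)
    for compound, grp in tests.groupby("compound"):
        ao = grp[grp["design"] == "acute_oral"]
        co = grp[grp["design"] == "chronic_oral"]
        if len(ao) < 2 or co.empty:
            continue
        chronic_lc50 = float(co["lc50_48h_or_10d_mg_kg"].iloc[0])
        ld = ao["ld50_48h_ug_bee"].astype(float)
        if ld.isna().any() or np.isnan(chronic_lc50):
            raise ValueError(f"missing LD50/LC50 values for {compound}")
        for idx, value in ld.items():
            others = ld.drop(idx)
            ratios = np.maximum(others / value, value / others)
            differs = ratios.min() >= factor if require_all_others else ratios.max() >= factor
            lower = float(tests.loc[idx, "lc50_48h_or_10d_mg_kg"]) < chronic_lc50
            flags.loc[idx] = bool(differs and lower)
    return tests[~flags].copy(), tests[flags].copy()


_PROFILE_COLUMNS = ["test_id", "treatment_id", "route_id", "unit", "t_start_d", "t_end_d", "level"]


def write_profiles_csv(
    path, profiles: Iterable[tuple[str, str, ExposureProfile]]
) -> None:
    """Write ``(test_id, treatment_id, profile)`` triples to CSV."""
    rows = []
    for test_id, treatment_id, p in profiles:
        for t0, t1, level in p.segments:
            rows.append((test_id, treatment_id, p.route_id, p.unit, t0, t1, level))
    pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(path, index=False)


def read_profiles_csv(path) -> list[tuple[str, str, ExposureProfile]]:
    df = pd.read_csv(path)
    missing = set(_PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV lacks columns {sorted(missing)}")
    out = []
    for (test_id, treatment_id, route_id), grp in df.groupby(
        ["test_id", "treatment_id", "route_id"], sort=False
    ):
        units = grp["unit"].unique()
        if len(units) != 1:
            raise ValueError(
                f"inconsistent units for {test_id}/{treatment_id} route {route_id}"
            )
        segs = tuple(
            (float(r.t_start_d), float(r.t_end_d), float(r.level))
            for r in grp.sort_values("t_start_d").itertuples()
        )
        out.append(
            (
                str(test_id),
                str(treatment_id),
                ExposureProfile(route_id=int(route_id), unit=str(units[0]), segments=segs),
            )
        )
    return out
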