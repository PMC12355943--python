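"""Forward simulation of multi-route buffered GUTS survival models.

The model family links piecewise-constant external exposure ``C_i(t)`` on one
or more uptake routes (contact, oral, ...) to survival through a linear
cascade of states:

* per-route buffer ``B_i`` (residue on the exoskeleton / in the gut),
  ``dB_i/dt = eta * (C_i(t) - B_i)``, ``B_i(0) = 0``;
* scaled damage ``D`` expressed in route-1 exposure units.  Under
  *concentration addition* (CA) one shared dominant rate constant acts on the
  weighted buffer sum, ``dD/dt = k_d * (sum_i w_i B_i - D)``; under *damage
  addition* (DA) each route keeps its own kinetics,
  ``dD_i/dt = k_{d,i} * (B_i - D_i)`` and ``D = sum_i w_i D_i``.

Damage drives one of two death mechanisms:

* *stochastic death* (SD): hazard ``kk * max(0, D - z) + hb``;
* *individual tolerance* (IT): thresholds are log-logistic across
  individuals (median ``alpha``, shape ``beta``) and an individual dies once
  its running-maximum damage exceeds its threshold.

Because exposure is piecewise constant the cascade has an exact
two-exponential solution per segment; that closed form is the default
backend.  A numeric ODE backend (``scipy.integrate.solve_ivp``) is provided
as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

HOUR = 1.0 / 24.0  # exposure discretization grid, in days

__all__ = [
    "HOUR",
    "ExposureProfile",
    "ModelSpec",
    "ParamSet",
    "Trajectory",
    "default_grid",
    "simulate",
    "survival_sd",
    "survival_it",
    "predict_scenario",
    "free_param_names",
    "paramset_from_vector",
]


@dataclass(frozen=True)
class ExposureProfile:
    """Piecewise-constant exposure trace for one uptake route.

    Segments are half-open intervals ``[t_start, t_end)`` in days; exposure
    is zero outside all segments.  Route 1 is contact by convention.
    """

    route_id: int
    unit: str
    segments: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        segs = tuple((float(a), float(b), float(c)) for a, b, c in self.segments)
        object.__setattr__(self, "segments", segs)
        prev_end = -np.inf
        for t0, t1, level in segs:
            if t1 <= t0:
                raise ValueError(f"segment [{t0}, {t1}) is empty or reversed")
            if t0 < prev_end:
                raise ValueError("exposure segments overlap or are unsorted")
            if level < 0:
                raise ValueError(f"negative exposure level {level}")
            prev_end = t1

    @property
    def breakpoints(self) -> np.ndarray:
        pts = [t for seg in self.segments for t in seg[:2]]
        return np.unique(np.asarray(pts, dtype=float))

    def level_at(self, t: float) -> float:
        for t0, t1, level in self.segments:
            if t0 <= t < t1:
                return level
        return 0.0

    def levels_on_intervals(self, grid: np.ndarray) -> np.ndarray:
        """Exposure level on each interval ``[grid[j], grid[j+1])``.

        Grid must contain every segment boundary for the result to be exact.
        """
        mid = 0.5 * (grid[:-1] + grid[1:])
        return np.asarray([self.level_at(t) for t in mid], dtype=float)


@dataclass(frozen=True)
class ModelSpec:
    """Model variant: route-combination rule, death mechanism, route count.

    ``eta`` (the buffer speed constant, per day) is a fixed structural
    constant of the buffer stage, never a calibration parameter.
    """

    combination: Literal["CA", "DA"]
    death: Literal["SD", "IT"]
    n_routes: int = 1
    eta: float = 2.0
    route_units: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.combination not in ("CA", "DA"):
            raise ValueError(f"unknown combination {self.combination!r}")
        if self.death not in ("SD", "IT"):
            raise ValueError(f"unknown death mechanism {self.death!r}")
        if self.n_routes < 1:
            raise ValueError("n_routes must be >= 1")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.route_units is not None:
            object.__setattr__(self, "route_units", tuple(self.route_units))
            if len(self.route_units) != self.n_routes:
                raise ValueError("route_units length must equal n_routes")

    @property
    def variant(self) -> str:
        return f"{self.combination}-{self.death}"


@dataclass(frozen=True)
class ParamSet:
    """Free/fixed parameter vector of one model variant.

    All thresholds and medians are expressed in route-1 exposure units;
    ``w[i]`` converts route-``i+1`` exposure into route-1 units and ``w[0]``
    is fixed at 1 for identifiability.
    """

    kd: tuple[float, ...]  # one entry (CA) or one per route (DA)
    w: tuple[float, ...] = (1.0,)
    z: float | None = None  # SD threshold, route-1 units
    kk: float | None = None  # SD killing rate, 1/(route-1 unit * day)
    alpha: float | None = None  # IT threshold median, route-1 units
    beta: float | None = None  # IT threshold shape (log-logistic)
    hb: float = 0.0  # background hazard, 1/day

    def __post_init__(self) -> None:
        kd = tuple(float(k) for k in np.atleast_1d(self.kd))
        w = tuple(float(x) for x in np.atleast_1d(self.w))
        object.__setattr__(self, "kd", kd)
        object.__setattr__(self, "w", w)
        if any(k <= 0 for k in kd):
            raise ValueError("kd entries must be > 0")
        if any(x <= 0 for x in w):
            raise ValueError("weights must be > 0")
        if abs(w[0] - 1.0) > 0:
            raise ValueError("w[0] must be exactly 1 (route-1 unit anchor)")
        for name in ("z", "kk", "alpha", "beta"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.hb < 0:
            raise ValueError("hb must be >= 0")

    def validate_for(self, spec: ModelSpec) -> None:
        n_kd = 1 if spec.combination == "CA" else spec.n_routes
        if len(self.kd) != n_kd:
            raise ValueError(
                f"{spec.combination} with {spec.n_routes} routes needs "
                f"{n_kd} kd value(s), got {len(self.kd)}"
            )
        if len(self.w) != spec.n_routes:
            raise ValueError(
                f"need {spec.n_routes} weights, got {len(self.w)}"
            )
        if spec.death == "SD" and (self.z is None or self.kk is None):
            raise ValueError("SD requires z and kk")
        if spec.death == "IT" and (self.alpha is None or self.beta is None):
            raise ValueError("IT requires alpha and beta")


@dataclass
class Trajectory:
    """Simulated state time courses on an evaluation grid (days)."""

    times: np.ndarray
    B: np.ndarray  # (n_routes, T) per-route buffers
    D: np.ndarray  # (T,) combined scaled damage, route-1 units
    S: np.ndarray  # (T,) survival probability
    B_sum: np.ndarray | None = None  # CA: weighted buffer sum
    D_routes: np.ndarray | None = None  # DA: per-route damages
    H: np.ndarray | None = None  # SD: cumulative hazard (incl. background)

    def survival_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.times, self.S)


def default_grid(
    profiles: Sequence[ExposureProfile],
    obs_times: Sequence[float] | None = None,
    horizon: float | None = None,
    resolution: float = HOUR,
) -> np.ndarray:
    """Union of exposure breakpoints, observation times and a regular grid."""
    pts = [np.array([0.0])]
    for p in profiles:
        if p.segments:
            pts.append(p.breakpoints)
    if obs_times is not None:
        pts.append(np.asarray(obs_times, dtype=float))
    end = horizon if horizon is not None else max(p.max() for p in pts)
    pts.append(np.arange(0.0, end + 0.5 * resolution, resolution))
    grid = np.unique(np.concatenate(pts))
    grid = grid[(grid >= 0.0) & (grid <= end + 1e-12)]
    # collapse near-duplicates produced by float unions
    keep = np.concatenate(([True], np.diff(grid) > 1e-12))
    return grid[keep]


def _damage_step(
    D0: float, A: float, Bc: float, kd: float, eta: float, tau: np.ndarray
) -> np.ndarray:
    """Exact damage response to a buffer ``B(tau) = A + Bc * exp(-eta*tau)``.

    Solves ``dD/dtau = kd * (B - D)`` from ``D(0) = D0``.  The ``kd == eta``
    resonance is handled by its ``tau * exp(-kd*tau)`` limit.
    """
    if abs(kd - eta) <= 1e-9 * (kd + eta):
        k = 0.5 * (kd + eta)
        e = np.exp(-k * tau)
        return A + (D0 - A) * e + k * Bc * tau * e
    coef = kd * Bc / (kd - eta)
    return (
        A
        + coef * np.exp(-eta * tau)
        + (D0 - A - coef) * np.exp(-kd * tau)
    )


def _states_analytic(
    spec: ModelSpec, params: ParamSet, profiles: Sequence[ExposureProfile], times: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Exact B/D states at ``times``; returns (B, D, B_sum, D_routes).

    Exposure is constant between consecutive breakpoints, so states are
    propagated segment-by-segment with the closed form evaluated vectorized
    at every requested time inside each segment.
    """
    N = spec.n_routes
    eta = spec.eta
    w = np.asarray(params.w)
    brk = (
        np.unique(np.concatenate([p.breakpoints for p in profiles]))
        if any(p.segments for p in profiles)
        else np.empty(0)
    )
    brk = brk[(brk > times[0]) & (brk < times[-1])]
    events = np.unique(np.concatenate([[times[0], times[-1]], brk]))
    levels = np.stack([p.levels_on_intervals(events) for p in profiles])  # (N, E-1)

    is_ca = spec.combination == "CA"
    kd = params.kd[0] if is_ca else None
    kds = None if is_ca else np.asarray(params.kd)

    B = np.empty((N, times.size))
    Dca = np.empty(times.size) if is_ca else None
    Dr = None if is_ca else np.empty((N, times.size))
    B[:, 0] = 0.0
    if is_ca:
        Dca[0] = 0.0
        D_state = 0.0
    else:
        Dr[:, 0] = 0.0
        D_state = np.zeros(N)
    B_state = np.zeros(N)

    for j in range(events.size - 1):
        a, b = events[j], events[j + 1]
        c = levels[:, j]
        mask = (times > a) & (times <= b)
        taus = times[mask] - a
        tau_all = np.append(taus, b - a)  # last entry advances the state
        decay = np.exp(-eta * tau_all)
        B_seg = c[:, None] + (B_state - c)[:, None] * decay[None, :]
        if is_ca:
            A = float(w @ c)
            Bc = float(w @ B_state) - A
            D_seg = _damage_step(D_state, A, Bc, kd, eta, tau_all)
            Dca[mask] = D_seg[:-1]
            D_state = D_seg[-1]
        else:
            D_seg = np.empty((N, tau_all.size))
            for i in range(N):
                D_seg[i] = _damage_step(
                    D_state[i], c[i], B_state[i] - c[i], kds[i], eta, tau_all
                )
            Dr[:, mask] = D_seg[:, :-1]
            D_state = D_seg[:, -1]
        B[:, mask] = B_seg[:, :-1]
        B_state = B_seg[:, -1]

    if is_ca:
        return B, Dca, w @ B, None
    return B, w @ Dr, None, Dr


def _states_numeric(
    spec: ModelSpec, params: ParamSet, profiles: Sequence[ExposureProfile], times: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Adaptive ODE backend, segment-stitched so C(t) is exactly constant
    within every integration interval."""
    N = spec.n_routes
    eta = spec.eta
    w = np.asarray(params.w)
    is_ca = spec.combination == "CA"
    n_states = N + (1 if is_ca else N)

    brk = np.unique(np.concatenate([p.breakpoints for p in profiles]))
    brk = brk[(brk > times[0]) & (brk < times[-1])]
    events = np.unique(np.concatenate([[times[0], times[-1]], brk]))

    out = np.empty((n_states, times.size))
    y = np.zeros(n_states)
    filled = np.zeros(times.size, dtype=bool)
    for a, b in zip(events[:-1], events[1:]):
        c = np.array([p.level_at(0.5 * (a + b)) for p in profiles])

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            dB = eta * (c - y[:N])
            if is_ca:
                dD = params.kd[0] * (w @ y[:N] - y[N])
                return np.concatenate([dB, [dD]])
            dD = np.asarray(params.kd) * (y[:N] - y[N:])
            return np.concatenate([dB, dD])

        mask = (times >= a - 1e-12) & (times <= b + 1e-12) & ~filled
        t_eval = np.unique(np.concatenate([[a, b], times[mask]]))
        sol = solve_ivp(
            rhs, (a, b), y, t_eval=t_eval, method="LSODA", rtol=1e-10, atol=1e-13
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed: {sol.message}")
        idx = np.searchsorted(t_eval, times[mask])
        out[:, mask] = sol.y[:, idx]
        filled |= mask
        y = sol.y[:, -1]

    B = out[:N]
    if is_ca:
        return B, out[N], w @ B, None
    Dr = out[N:]
    return B, w @ Dr, None, Dr


def survival_sd(
    times: np.ndarray, D: np.ndarray, z: float, kk: float, hb: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Stochastic-death survival for a piecewise-linear damage trace.

    ``S(t) = exp(-int_0^t [kk * max(0, D - z) + hb] dtau)``.  The excess
    integral is evaluated exactly on the linear interpolant of ``D`` between
    grid points (threshold crossings solved per interval).

    Returns ``(H, S)`` with ``H`` the cumulative hazard including background.
    """
    times = np.asarray(times, dtype=float)
    D = np.asarray(D, dtype=float)
    if z <= 0 or kk <= 0:
        raise ValueError("z and kk must be > 0")
    if hb < 0:
        raise ValueError("hb must be >= 0")
    if np.any(D < 0):
        raise ValueError("damage trace must be non-negative")
    d0 = D[:-1] - z
    d1 = D[1:] - z
    dt = np.diff(times)
    both_neg = (d0 <= 0) & (d1 <= 0)
    both_pos = (d0 >= 0) & (d1 >= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tri = 0.5 * np.maximum(np.maximum(d0, d1), 0.0) ** 2 / np.abs(d1 - d0)
    area = np.where(
        both_neg, 0.0, np.where(both_pos, 0.5 * (d0 + d1), tri)
    ) * dt
    H = np.concatenate(([0.0], np.cumsum(kk * area))) + hb * (times - times[0])
    return H, np.exp(-H)


def survival_it(
    times: np.ndarray, D: np.ndarray, alpha: float, beta: float, hb: float = 0.0
) -> np.ndarray:
    """Individual-tolerance survival: log-logistic threshold distribution
    applied to the running maximum of the combined damage."""
    times = np.asarray(times, dtype=float)
    D = np.asarray(D, dtype=float)
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    if hb < 0:
        raise ValueError("hb must be >= 0")
    M = np.maximum.accumulate(np.maximum(D, 0.0))
    F = np.zeros_like(M)
    pos = M > 0
    F[pos] = 1.0 / (1.0 + (M[pos] / alpha) ** (-beta))
    return (1.0 - F) * np.exp(-hb * (times - times[0]))


def simulate(
    spec: ModelSpec,
    params: ParamSet,
    profiles: Sequence[ExposureProfile],
    times: np.ndarray,
    backend: Literal["analytic", "numeric"] = "analytic",
) -> Trajectory:
    """Simulate buffer, damage and survival for one exposure scenario.

    ``times`` must be sorted and start at 0.  The stochastic-death hazard is
    integrated on the piecewise-linear damage interpolant over ``times``, so
    the grid should include at least the hourly discretization points (use
    :func:`default_grid`).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must be a 1-d grid with at least two points")
    if times[0] != 0.0:
        raise ValueError("time grid must start at 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if len(profiles) != spec.n_routes:
        raise ValueError(
            f"expected {spec.n_routes} exposure profiles, got {len(profiles)}"
        )
    params.validate_for(spec)

    if backend not in ("analytic", "numeric"):
        raise ValueError(f"unknown backend {backend!r}")
    states = _states_analytic if backend == "analytic" else _states_numeric
    B, D, B_sum, D_routes = states(spec, params, profiles, times)
    D = np.maximum(D, 0.0)  # guard against -1e-18 round-off

    if spec.death == "SD":
        H, S = survival_sd(times, D, params.z, params.kk, params.hb)
    else:
        H = None
        S = survival_it(times, D, params.alpha, params.beta, params.hb)
    return Trajectory(times=times, B=B, D=D, S=S, B_sum=B_sum, D_routes=D_routes, H=H)


def predict_scenario(
    spec: ModelSpec,
    params: ParamSet,
    contact_dose: float,
    oral_level: float,
    oral_start: float,
    oral_duration: float,
    horizon: float,
    backend: Literal["analytic", "numeric"] = "analytic",
) -> Trajectory:
    """Combined-exposure scenario: a 1-h contact pulse at t=0 plus a constant
    oral exposure window ``[oral_start, oral_start + oral_duration)``.

    Units follow the two-route honeybee convention: contact dose in ug
    a.i./bee (route 1), oral level in mg a.i./kg food (route 2).
    """
    if spec.n_routes != 2:
        raise ValueError("predict_scenario requires a two-route (contact+oral) spec")
    if contact_dose < 0 or oral_level < 0:
        raise ValueError("exposure levels must be >= 0")
    if oral_start < 0 or oral_duration < 0:
        raise ValueError("oral window must be non-negative")
    if oral_start + oral_duration > horizon + 1e-12:
        raise ValueError("oral exposure window extends beyond the horizon")
    contact = ExposureProfile(
        route_id=1,
        unit="ug a.i./bee",
        segments=((0.0, HOUR, contact_dose),) if contact_dose > 0 else (),
    )
    oral = ExposureProfile(
        route_id=2,
        unit="mg a.i./kg food",
        segments=((oral_start, oral_start + oral_duration, oral_level),)
        if oral_level > 0 and oral_duration > 0
        else (),
    )
    grid = default_grid([contact, oral], horizon=horizon)
    return simulate(spec, params, [contact, oral], grid, backend=backend)


def free_param_names(spec: ModelSpec, include_hb: bool = True) -> list[str]:
    """Ordered names of the free parameters of a variant.

    CA: ``kd, w_2..w_N, <death params>``; DA: ``kd_1..kd_N, w_2..w_N,
    <death params>``; plus ``hb`` when it is calibrated.
    """
    names: list[str] = []
    if spec.combination == "CA":
        names.append("kd")
    else:
        names.extend(f"kd_{i + 1}" for i in range(spec.n_routes))
    names.extend(f"w_{i + 1}" for i in range(1, spec.n_routes))
    names.extend(("z", "kk") if spec.death == "SD" else ("alpha", "beta"))
    if include_hb:
        names.append("hb")
    return names


def paramset_from_vector(
    spec: ModelSpec, theta: Sequence[float], hb: float | None = None
) -> ParamSet:
    """Build a :class:`ParamSet` from a flat free-parameter vector in the
    order of :func:`free_param_names` (``hb`` given either in the vector or
    as the fixed keyword)."""
    theta = [float(v) for v in theta]
    include_hb = hb is None
    names = free_param_names(spec, include_hb=include_hb)
    if len(theta) != len(names):
        raise ValueError(f"expected {len(names)} values {names}, got {len(theta)}")
    vals = dict(zip(names, theta))
    n_kd = 1 if spec.combination == "CA" else spec.n_routes
    if spec.combination == "CA":
        kd = (vals["kd"],)
    else:
        kd = tuple(vals[f"kd_{i + 1}"] for i in range(n_kd))
    w = (1.0,) + tuple(vals[f"w_{i + 1}"] for i in range(1, spec.n_routes))
    kwargs: dict = {"kd": kd, "w": w, "hb": vals["hb"] if include_hb else hb}
    if spec.death == "SD":
        kwargs.update(z=vals["z"], kk=vals["kk"])
    else:
        kwargs.update(alpha=vals["alpha"], beta=vals["beta"])
    return ParamSet(**kwargs)
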