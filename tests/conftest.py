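import numpy as np
import pytest

from bufferguts import (
    ExposureProfile,
    ModelSpec,
    ParamSet,
    default_grid,
)


@pytest.fixture
def contact_pulse():
    """1-h topical pulse at t=0, 0.3 ug a.i./bee."""
    return ExposureProfile(1, "ug a.i./bee", ((0.0, 1.0 / 24.0, 0.3),))


@pytest.fixture
def oral_windows():
    """Two oral exposure windows, mg a.i./kg food."""
    return ExposureProfile(2, "mg a.i./kg food", ((0.2, 0.5, 0.04), (1.0, 3.0, 0.01)))


@pytest.fixture
def two_route_grid(contact_pulse, oral_windows):
    return default_grid([contact_pulse, oral_windows], horizon=5.0)


def random_instance(rng, n_routes=2, combination="CA", death="SD"):
    """Random spec/params/profiles/grid for property checks."""
    spec = ModelSpec(
        combination=combination,
        death=death,
        n_routes=n_routes,
        eta=float(rng.uniform(0.5, 5.0)),
    )
    n_kd = 1 if combination == "CA" else n_routes
    kwargs = dict(
        kd=tuple(rng.uniform(0.1, 3.0, n_kd)),
        w=(1.0,) + tuple(rng.uniform(0.01, 30.0, n_routes - 1)),
        hb=float(rng.uniform(0.0, 0.05)),
    )
    if death == "SD":
        kwargs.update(z=float(rng.uniform(0.005, 0.2)), kk=float(rng.uniform(0.1, 50.0)))
    else:
        kwargs.update(alpha=float(rng.uniform(0.005, 0.2)), beta=float(rng.uniform(0.5, 6.0)))
    params = ParamSet(**kwargs)
    profiles = []
    for route in range(1, n_routes + 1):
        n_seg = rng.integers(0, 3)
        segs, t = [], 0.0
        for _ in range(n_seg):
            t0 = t + rng.uniform(0.0, 1.0)
            t1 = t0 + rng.uniform(1.0 / 24.0, 2.0)
            segs.append((t0, t1, float(rng.uniform(0.0, 1.0))))
            t = t1
        profiles.append(ExposureProfile(route, f"unit{route}", tuple(segs)))
    grid = default_grid(profiles, horizon=6.0)
    return spec, params, profiles, grid
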