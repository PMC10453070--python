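"""Bioconvection experiments: initial conditions, plume diagnostics, presets.

The baseline experiment places a dense cell layer near the fluid-air
interface of the shallow chamber (-3,3) x (0,1): q = 1 above the weakly
perturbed line y = 0.499 - 0.01 sin((x - 1.5) pi) and q = 0.5 below, with
saturated oxygen c = 1 and fluid at rest.  The layer is Rayleigh-Taylor
unstable: cells swim up the oxygen gradient, overload the interface and sink
as finger- then mushroom-shaped plumes.  A random-layer variant draws
q0 = 0.8 + 0.2*U(0,1) per cell.

The quantitative diagnostic is the plume front depth: the lowest cell-centre
y among cells with q above a threshold (default 0.75, midway between the
layer and background densities), and the time at which that front first
crosses the domain midline after having been above it.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .grid import GridSpec
from .params import PhysicalParams
from .timeloop import RunConfig

__all__ = ["initial_plume_layer", "random_initial_density",
           "plume_front_depth", "first_crossing_time", "preset_config",
           "PRESETS"]


def initial_plume_layer(grid: GridSpec):
    """Perturbed-layer initial data (q0, c0, v1, v2) on the chamber grid:
    q = 1 above y = 0.499 - 0.01 sin((x - 1.5) pi), else 0.5; c = 1; u = 0."""
    X, Y = np.meshgrid(grid.xc, grid.yc, indexing="ij")
    thr = 0.499 - 0.01 * np.sin((X - 1.5) * np.pi)
    q0 = np.where(Y > thr, 1.0, 0.5)
    c0 = np.ones(grid.center_shape)
    return q0, c0, np.zeros(grid.v1_shape), np.zeros(grid.v2_shape)


def random_initial_density(grid: GridSpec, seed: int) -> np.ndarray:
    """Uniform random layer q0 = 0.8 + 0.2*U(0,1) per cell centre,
    reproducible for a given seed."""
    rng = np.random.default_rng(seed)
    return 0.8 + 0.2 * rng.random(grid.center_shape)


def plume_front_depth(q: np.ndarray, grid: GridSpec,
                      threshold: float = 0.75, warn: bool = True) -> float:
    """Lowest cell-centre y with q >= threshold; +inf if no cell qualifies
    (with a diagnostic warning when the threshold misses the field's range
    entirely)."""
    if not (q.min() < threshold < q.max()):
        if warn:
            warnings.warn(
                f"front threshold {threshold} outside field range "
                f"({q.min():.3g}, {q.max():.3g})", stacklevel=2)
        return math.inf
    mask = q >= threshold
    j = np.where(mask.any(axis=0))[0]
    return float(grid.yc[j[0]])


def first_crossing_time(times, depths, y_mid: float = 0.5):
    """First time the front depth drops below ``y_mid`` after having been at
    or above it (a genuine descent across the midline).

    The initial layer's perturbation can dip below the midline at t = 0;
    requiring a preceding above-line record keeps the statistic from firing
    on the initial condition.  Falls back to the first below-line time if the
    front never retracts above the line; ``None`` if it never crosses.
    """
    times = np.asarray(times, dtype=float)
    depths = np.asarray(depths, dtype=float)
    below = depths < y_mid
    if not below.any():
        return None
    above_before = np.concatenate(([False], np.maximum.accumulate(
        depths >= y_mid)[:-1]))
    genuine = below & above_before
    if genuine.any():
        return float(times[np.argmax(genuine)])
    if (depths >= y_mid).any():
        # the front retracted above the line and never came back below
        return None
    return float(times[np.argmax(below)])


# --------------------------------------------------------------------------
# presets reproducing the parameter studies
# --------------------------------------------------------------------------

_BASE = dict(alpha=10.0, Sc=500.0, eta=1.0, beta=50.0, gamma=5000.0, zeta=5.0)

#: parameter sets of the plume studies; all share alpha=10, Sc=500, eta=1
PRESETS = {
    "zeta5": dict(_BASE),
    "zeta25": dict(_BASE, zeta=25.0),
    "zeta50": dict(_BASE, zeta=50.0),
    "beta10gamma1000": dict(_BASE, beta=10.0, gamma=1000.0),
    "beta30gamma3000": dict(_BASE, beta=30.0, gamma=3000.0),
    "random": dict(_BASE),
}


def preset_config(name: str, Nx: int = 300, Ny: int = 200, dt: float = 1e-4,
                  T: float = 0.15, seed: int = 0,
                  snapshot_times=(), **overrides) -> RunConfig:
    """RunConfig for a named plume preset on (-3,3) x (0,1).

    Defaults match the baseline study: hx = 0.02, hy = 0.005, dt = 1e-4.
    ``'random'`` switches to the random-layer initial density (seeded).
    Pass smaller Nx/Ny/dt for quick qualitative runs.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = PhysicalParams(**PRESETS[name])
    ic = "random" if name == "random" else "plume"
    cfg = RunConfig(xa=-3.0, xb=3.0, ya=0.0, yb=1.0, Nx=Nx, Ny=Ny, dt=dt, T=T,
                    params=params, ic=ic, seed=seed,
                    snapshot_times=tuple(snapshot_times),
                    track_front=True, **overrides)
    return cfg
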