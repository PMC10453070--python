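"""Time-stepping orchestration: Steps 1-5 per step, history management,
Richardson extrapolation and run-level bookkeeping.

Per time step:

1. velocity predictor + ADI viscous correction  -> u^n
2. dimension-split pressure update              -> psi^{n-1/2}, p^{n-1/2}
3-4. chemotaxis pass A: oxygen then cells over one full dt with u^n
     chemotaxis pass B: two half-steps, the first convecting with the
     half-time velocity (u^{n-1} + u^n)/2, the second with u^n
5. Richardson combination 2*(half-step result) - (full-step result), which
   cancels the O(dt) splitting error of the scalar passes and restores
   second order in time.

The velocity/pressure pair is computed once per step (Steps 1-2 are already
second order); only the scalar pair is doubled.  Histories are rotated with
the extrapolated fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any, Callable

import numpy as np
import pandas as pd

from .chemo import REACTION_WEIGHTS, cell_update, half_time_density, oxygen_update
from .fluid import FluidHistory, fluid_advance
from .grid import BCSpec, GridSpec, build_grid, face_divergence, velocity_to_centers
from .params import PhysicalParams

__all__ = ["State", "RunConfig", "RunResult", "Simulation",
           "richardson_combine", "half_time_velocity", "run"]


def richardson_combine(full: np.ndarray, half: np.ndarray) -> np.ndarray:
    """2*half - full: cancels the leading O(dt) error of the split passes."""
    if full.shape != half.shape:
        raise ValueError("shape mismatch in extrapolation")
    return 2.0 * half - full


def half_time_velocity(u_prev, u_new):
    """Componentwise average (u^{n-1} + u^n)/2 — the velocity at t^{n-1/2}."""
    return tuple(0.5 * (a + b) for a, b in zip(u_prev, u_new))


@dataclass
class State:
    """Discrete unknowns at one time level plus the multistep history."""

    n: int
    t: float
    v1: np.ndarray
    v2: np.ndarray
    p: np.ndarray    # p^{n-1/2}
    psi: np.ndarray  # psi^{n-1/2}
    q: np.ndarray
    c: np.ndarray
    v1_prev: np.ndarray
    v2_prev: np.ndarray
    q_prev: np.ndarray

    def check_finite(self):
        for name in ("v1", "v2", "p", "psi", "q", "c"):
            a = getattr(self, name)
            if not np.all(np.isfinite(a)):
                raise FloatingPointError(
                    f"non-finite values in field {name!r} at step {self.n} "
                    f"(t = {self.t:g})")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; maps 1:1 onto a flat YAML file."""

    xa: float = -3.0
    xb: float = 3.0
    ya: float = 0.0
    yb: float = 1.0
    Nx: int = 300
    Ny: int = 200
    dt: float = 1e-4
    T: float = 0.1
    params: PhysicalParams = field(default_factory=PhysicalParams)
    bc_mode: str = "model"            # 'model' | 'mms'
    ghost_mode: str = "literal"       # 'literal' | 'reflected'
    ic: str | Callable = "plume"      # 'plume' | 'random' | 'zero' | callable
    seed: int = 0
    snapshot_times: tuple = ()
    richardson: bool = True
    reaction_weights: str = "consistent"
    chemo_form: str = "conservative"
    q_top_closure: str = "auto"   # 'flux' | 'exp' | 'auto' (by chemo form)
    mms_case: Any = None
    track_front: bool = False
    front_threshold: float = 0.75
    stop_front_below: float | None = None
    cfl_warn: bool = True

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T < self.dt:
            raise ValueError("T must be at least one time step")
        if self.reaction_weights not in REACTION_WEIGHTS:
            raise ValueError(f"unknown reaction weights {self.reaction_weights!r}")
        if isinstance(self.params, dict):
            self.params = PhysicalParams(**self.params)

    def to_yaml(self, path) -> None:
        """Write the config as a flat key/value YAML file (params inlined
        with a ``param_`` prefix)."""
        import yaml
        skip = {"params", "mms_case", "ic", "snapshot_times"}
        d = {k: v for k, v in self.__dict__.items() if k not in skip}
        if isinstance(self.ic, str):
            d["ic"] = self.ic
        d["snapshot_times"] = list(self.snapshot_times)
        for k, v in self.params.as_dict().items():
            d[f"param_{k}"] = v
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            d = yaml.safe_load(fh)
        pkw = {k[6:]: v for k, v in d.items() if k.startswith("param_")}
        kw = {k: v for k, v in d.items() if not k.startswith("param_")}
        if "snapshot_times" in kw:
            kw["snapshot_times"] = tuple(kw["snapshot_times"])
        return cls(params=PhysicalParams(**pkw), **kw)

    def scheme_metadata(self) -> dict:
        return {
            "bc_mode": self.bc_mode, "ghost_mode": self.ghost_mode,
            "richardson": self.richardson,
            "reaction_weights": self.reaction_weights,
            "chemo_form": self.chemo_form,
            "q_top_closure": self.q_top_closure, "seed": self.seed,
            "dt": self.dt, "T": self.T, "Nx": self.Nx, "Ny": self.Ny,
            "domain": [self.xa, self.xb, self.ya, self.yb],
            "params": self.params.as_dict(),
        }


@dataclass
class RunResult:
    config: RunConfig
    grid: GridSpec
    diagnostics: pd.DataFrame
    snapshots: dict
    state: State

    @property
    def first_crossing_time(self):
        from .experiments import first_crossing_time
        if "front_depth" not in self.diagnostics:
            return None
        return first_crossing_time(self.diagnostics["t"].to_numpy(),
                                   self.diagnostics["front_depth"].to_numpy(),
                                   y_mid=0.5)


class Simulation:
    """Stateful driver built from a :class:`RunConfig`."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.grid = build_grid(config.xa, config.xb, config.ya, config.yb,
                               config.Nx, config.Ny)
        self.params = config.params
        if config.bc_mode == "mms":
            if config.mms_case is None:
                from .mms import build_mms_case
                config.mms_case = build_mms_case(config.params)
            self.bc = BCSpec(mode="mms", ghost_mode=config.ghost_mode,
                             case=config.mms_case)
            self.forcing = config.mms_case
        else:
            self.bc = BCSpec(mode="model", ghost_mode=config.ghost_mode)
            self.forcing = None
        self.weights = REACTION_WEIGHTS[config.reaction_weights]
        self.state = self._initial_state()
        self._cfl_warned = False

    # -- initial conditions -------------------------------------------------
    def _initial_state(self) -> State:
        g = self.grid
        ic = self.config.ic
        zc = np.zeros(g.center_shape)
        v1 = np.zeros(g.v1_shape)
        v2 = np.zeros(g.v2_shape)
        if callable(ic):
            q0, c0 = ic(g)
        elif ic == "plume":
            from .experiments import initial_plume_layer
            q0, c0, v1, v2 = initial_plume_layer(g)
        elif ic == "random":
            from .experiments import initial_plume_layer, random_initial_density
            _, c0, v1, v2 = initial_plume_layer(g)
            q0 = random_initial_density(g, self.config.seed)
        elif ic == "zero":
            q0, c0 = zc.copy(), zc.copy()
        elif ic == "mms":
            # manufactured fields all vanish at t = 0
            q0, c0 = zc.copy(), zc.copy()
        else:
            raise ValueError(f"unknown initial condition {ic!r}")
        return State(n=0, t=0.0, v1=v1, v2=v2, p=zc.copy(), psi=zc.copy(),
                     q=q0, c=c0, v1_prev=v1.copy(), v2_prev=v2.copy(),
                     q_prev=q0.copy())

    # -- one step -----------------------------------------------------------
    def advance(self) -> State:
        s = self.state
        cfg = self.config
        dt = cfg.dt
        t_new = (s.n + 1) * dt

        q_star = half_time_density(s.q, s.q_prev)
        hist = FluidHistory(s.v1, s.v2, s.v1_prev, s.v2_prev, s.p, s.psi, dt)
        v1n, v2n, psi_n, p_n = fluid_advance(
            hist, q_star, self.params, self.grid, self.bc,
            t_new=t_new, forcing=self.forcing)

        v1c, v2c = velocity_to_centers(v1n, v2n)
        kw = dict(params=self.params, grid=self.grid, bc=self.bc,
                  forcing=self.forcing)
        # pass A: one full step
        qh = half_time_density(s.q, s.q_prev, (1.5, -0.5))
        cA = oxygen_update(s.c, qh, v1c, v2c, tau=dt, t_start=s.t,
                           weights=self.weights, **kw)
        qA = cell_update(s.q, cA, v1c, v2c, tau=dt, t_start=s.t,
                         chemo_form=cfg.chemo_form,
                         q_top_closure=cfg.q_top_closure, **kw)
        if cfg.richardson:
            # pass B: two half steps; convection velocity at each
            # sub-interval's endpoint
            v1h, v2h = half_time_velocity((s.v1, s.v2), (v1n, v2n))
            v1hc, v2hc = velocity_to_centers(v1h, v2h)
            qh1 = half_time_density(s.q, s.q_prev, (1.25, -0.25))
            cB = oxygen_update(s.c, qh1, v1hc, v2hc, tau=dt / 2, t_start=s.t,
                               weights=self.weights, **kw)
            qB = cell_update(s.q, cB, v1hc, v2hc, tau=dt / 2, t_start=s.t,
                             chemo_form=cfg.chemo_form,
                             q_top_closure=cfg.q_top_closure, **kw)
            qh2 = half_time_density(s.q, s.q_prev, (1.75, -0.75))
            cB2 = oxygen_update(cB, qh2, v1c, v2c, tau=dt / 2,
                                t_start=s.t + dt / 2, weights=self.weights,
                                **kw)
            qB2 = cell_update(qB, cB2, v1c, v2c, tau=dt / 2,
                              t_start=s.t + dt / 2,
                              chemo_form=cfg.chemo_form,
                              q_top_closure=cfg.q_top_closure, **kw)
            c_new = richardson_combine(cA, cB2)
            q_new = richardson_combine(qA, qB2)
        else:
            c_new, q_new = cA, qA

        new = State(n=s.n + 1, t=t_new, v1=v1n, v2=v2n, p=p_n, psi=psi_n,
                    q=q_new, c=c_new, v1_prev=s.v1, v2_prev=s.v2,
                    q_prev=s.q)
        new.check_finite()
        if cfg.cfl_warn and not self._cfl_warned:
            umax = max(np.abs(v1n).max(), np.abs(v2n).max())
            if dt * umax / min(self.grid.hx, self.grid.hy) > 1.0:
                warnings.warn(
                    f"convective Courant number {dt * umax / min(self.grid.hx, self.grid.hy):.2f} "
                    f"> 1 at step {new.n}; explicit convection may be inaccurate",
                    stacklevel=2)
                self._cfl_warned = True
        self.state = new
        return new

    # -- full run -----------------------------------------------------------
    def run(self) -> RunResult:
        cfg = self.config
        g = self.grid
        n_steps = int(round(cfg.T / cfg.dt))
        snap_steps = {}
        for ts in cfg.snapshot_times:
            k = int(round(ts / cfg.dt))
            snap_steps.setdefault(min(max(k, 1), n_steps), ts)
        rows = []
        snapshots = {}
        cell_area = g.hx * g.hy
        seen_above = False
        if cfg.track_front:
            from .experiments import plume_front_depth
        for _ in range(n_steps):
            s = self.advance()
            div = face_divergence(s.v1, s.v2, g)
            row = {
                "step": s.n, "t": s.t,
                "mass": float(s.q.sum() * cell_area),
                "div_l2": float(np.sqrt(np.mean(div**2))),
                "q_min": float(s.q.min()), "q_max": float(s.q.max()),
                "c_min": float(s.c.min()), "c_max": float(s.c.max()),
            }
            if cfg.track_front:
                row["front_depth"] = plume_front_depth(
                    s.q, g, cfg.front_threshold, warn=False)
            rows.append(row)
            if s.n in snap_steps:
                snapshots[snap_steps[s.n]] = {
                    "step": s.n, "t": s.t, "q": s.q.copy(), "c": s.c.copy(),
                    "v1": s.v1.copy(), "v2": s.v2.copy(), "p": s.p.copy(),
                }
            if cfg.stop_front_below is not None and cfg.track_front:
                # stop once the plume has genuinely crossed: the front must
                # first retract to (or start) above the line, then drop below
                if row["front_depth"] >= cfg.stop_front_below:
                    seen_above = True
                elif seen_above:
                    break
        diag = pd.DataFrame(rows)
        return RunResult(config=cfg, grid=g, diagnostics=diag,
                         snapshots=snapshots, state=self.state)


def run(config: RunConfig) -> RunResult:
    """Run a configured simulation to its final time; deterministic for a
    given config and seed."""
    return Simulation(config).run()
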