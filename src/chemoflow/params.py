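"""Model parameters of the dimensionless chemotaxis-Navier-Stokes system.

The dimensionless groups are

    alpha = chi_q * c_air / alpha_n          (chemotactic sensitivity)
    beta  = q_r * L^2 / (c_air * alpha_n)    (oxygen consumption rate)
    gamma = V_b * q_r * g * (rho_b - rho) * L^3 / (eta * alpha_n)  (buoyancy)
    zeta  = alpha_c / alpha_n                (oxygen/cell diffusivity ratio)
    Sc    = eta / (alpha_n * rho)            (Schmidt number)

with L, q_r characteristic length and cell density, c_air the air oxygen
concentration, V_b the cell volume, g gravity, rho_b/rho cell/fluid density,
eta the dynamic viscosity and alpha_n, alpha_c the cell and oxygen
diffusivities, chi_q the chemotactic sensitivity coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

__all__ = ["PhysicalParams", "DimensionalConstants", "dimensionless_parameters"]


@dataclass
class PhysicalParams:
    """Dimensionless constants of the coupled system.

    ``chi`` weights the divergence correction in the pressure update
    (0 < chi <= 1, fixed at 1/2); ``eps`` sets the sharpness of the oxygen
    cut-off r(c) = (tanh((c - 0.3)/eps) + 1)/2; ``eta`` is the dimensionless
    viscosity appearing only in the chi*eta divergence correction.
    ``r_const`` overrides r(c) with a constant (the convergence study sets
    r = 1).
    """

    alpha: float = 10.0
    beta: float = 50.0
    gamma: float = 5000.0
    zeta: float = 5.0
    Sc: float = 500.0
    eta: float = 1.0
    chi: float = 0.5
    eps: float = 0.01
    r_const: float | None = None

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "zeta", "Sc", "eta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 < self.chi <= 1.0:
            raise ValueError("chi must satisfy 0 < chi <= 1")
        if self.eps <= 0:
            raise ValueError("eps must be positive")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class DimensionalConstants:
    """Dimensional constants entering the nondimensionalization (SI units)."""

    L: float          # characteristic length [m]
    qr: float         # characteristic cell density [cells/m^3]
    cair: float       # air oxygen concentration [mol/m^3]
    Vb: float         # cell volume [m^3]
    g: float          # gravitational acceleration [m/s^2]
    rho_b: float      # cell density [kg/m^3]
    rho: float        # fluid density [kg/m^3]
    eta: float        # dynamic viscosity [kg/(m s)]
    chi_q: float      # chemotactic sensitivity
    alpha_n: float    # cell diffusivity [m^2/s]
    alpha_c: float    # oxygen diffusivity [m^2/s]

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")


def dimensionless_parameters(consts: DimensionalConstants) -> PhysicalParams:
    """Convert dimensional constants to the dimensionless parameter set."""
    c = consts
    alpha = c.chi_q * c.cair / c.alpha_n
    beta = c.qr * c.L**2 / (c.cair * c.alpha_n)
    gamma = c.Vb * c.qr * c.g * (c.rho_b - c.rho) * c.L**3 / (c.eta * c.alpha_n)
    zeta = c.alpha_c / c.alpha_n
    Sc = c.eta / (c.alpha_n * c.rho)
    return PhysicalParams(alpha=alpha, beta=beta, gamma=gamma, zeta=zeta, Sc=Sc)
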