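"""Steady states of the thin film and their response to small perturbations.

Equilibria of the thin-film model have spatially uniform polymer fraction
theta* and cell density n* satisfying the surface force balance

    mu_s(theta*) - mu_s^e + theta* G(n*) = 0,

while the film height may stay non-uniform.  For a film prepared from
uniform initial data (theta_I, n_I) mass conservation ties the equilibrium
to the initial state: h* = sqrt(theta_I/theta*), n* = n_I theta*/theta_I.

Around an equilibrium scaled so that h* = n* = L* = 1, a cosine
perturbation of wavenumber gamma = Z*pi (Z a positive integer, forced by
the no-flux end conditions) evolves at short times according to closed-form
profiles; the growth or decay of the theta_p and h perturbations is
governed solely by the sign of

    z = theta* f''(theta*) - tau0/(1+lam) - theta* 2 tau0 N01/(1+lam)^2,

with z > 0 meaning decay (stability).  The cell perturbation additionally
feels diffusion, which is always stabilising.  These closed forms double as
an independent oracle for the PDE solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List

import numpy as np
from scipy.optimize import brentq

from .potentials import GelParameters, equilibrium_residual, f_second

__all__ = [
    "EquilibriumPoint",
    "PerturbationSpec",
    "StabilityReport",
    "find_equilibria",
    "z_statistic",
    "perturbation_growth_factor",
    "small_time_solution",
    "stability_report",
]


@dataclass(frozen=True)
class EquilibriumPoint:
    """An interior root of the equilibrium residual, dressed with the
    uniform-film quantities it implies for given initial data."""

    theta_star: float
    n_star: float
    h_star: float
    L_star: float
    residual_at_root: float

    def rounded(self, ndigits: int = 2) -> tuple:
        return (
            round(self.theta_star, ndigits),
            round(self.n_star, ndigits),
            round(self.h_star, ndigits),
            round(self.L_star, ndigits),
        )


@dataclass(frozen=True)
class PerturbationSpec:
    """Cosine perturbation of a uniform equilibrium.

    theta_p is perturbed by +eps*cos(gamma X), n by +eps*N01*cos(gamma X)
    and h by -eps*H01*cos(gamma X) (height moves opposite to composition).
    ``delta`` is the short-time scale: profiles are evaluated at
    T = delta * T_hat with delta << eps << 1.
    """

    Z: int = 1
    eps: float = 0.01
    delta: float = 1e-3
    N01: float = 1.0
    H01: float = 1.0

    def __post_init__(self) -> None:
        if not (isinstance(self.Z, (int, np.integer)) and self.Z >= 1):
            raise ValueError(f"mode Z must be a positive integer, got {self.Z}")
        if not 0 < self.eps < 1:
            raise ValueError(f"eps must lie in (0,1), got {self.eps}")
        if not 0 < self.delta:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.delta >= self.eps:
            raise ValueError(
                "short-time scale delta must be << perturbation amplitude eps"
                f" (got delta={self.delta}, eps={self.eps})"
            )

    @property
    def gamma(self) -> float:
        """Wavenumber gamma = Z*pi (no-flux conditions at X = 0, 1)."""
        return self.Z * math.pi


@dataclass(frozen=True)
class StabilityReport:
    """Verdicts for a perturbed uniform equilibrium."""

    theta_star: float
    z: float
    growth_rate_theta_h: float
    growth_rate_n: float
    verdict_theta_h: str  # "growing" | "decaying"
    verdict_n: str

    def to_dict(self) -> dict:
        return {
            "theta_star": self.theta_star,
            "z": self.z,
            "growth_rate_theta_h": self.growth_rate_theta_h,
            "growth_rate_n": self.growth_rate_n,
            "verdict_theta_h": self.verdict_theta_h,
            "verdict_n": self.verdict_n,
        }


def find_equilibria(
    theta_I: float,
    n_I: float,
    params: GelParameters,
    bracket: tuple = (1e-6, 1.0 - 1e-6),
    panels: int = 10_000,
    merge_tol: float = 1e-4,
) -> List[EquilibriumPoint]:
    """All interior equilibria reachable from uniform initial data.

    Mass conservation slaves the cell density to theta along the uniform
    trajectory, n = n_I * theta / theta_I, so equilibria are the interior
    roots of g(theta) = residual(theta, n_I theta / theta_I).  A dense sign
    scan over ``panels`` panels brackets every root; Brent refinement
    polishes each to |g| < 1e-13.  The trivial fully-dissolved root at
    theta -> 0 is excluded by the bracket.  Roots closer than ``merge_tol``
    are merged.  Returns an empty list when no interior root exists.
    """
    if not 0.0 < theta_I < 1.0:
        raise ValueError(f"theta_I must lie in (0,1), got {theta_I}")

    def g(theta):
        return equilibrium_residual(theta, n_I * theta / theta_I, params)

    lo, hi = bracket
    grid = np.linspace(lo, hi, panels + 1)
    vals = g(grid)
    roots: List[float] = []
    sign = np.sign(vals)
    for i in range(panels):
        if vals[i] == 0.0:
            roots.append(float(grid[i]))
        elif sign[i] * sign[i + 1] < 0:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-15, rtol=8.9e-16))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))

    merged: List[float] = []
    for r in sorted(roots):
        if not merged or r - merged[-1] > merge_tol:
            merged.append(r)

    out = []
    for theta_star in merged:
        h_star = math.sqrt(theta_I / theta_star)
        out.append(
            EquilibriumPoint(
                theta_star=theta_star,
                n_star=n_I * theta_star / theta_I,
                h_star=h_star,
                L_star=h_star,
                residual_at_root=float(g(theta_star)),
            )
        )
    return out


def z_statistic(theta_star: float, N01: float, params: GelParameters) -> float:
    """Stability statistic z for a cosine-perturbed uniform equilibrium.

    z = theta* f''(theta*) - tau0/(1+lam) - theta* 2 tau0 N01 / (1+lam)^2.
    Perturbations of theta_p and h decay iff z > 0.  The equilibrium is
    assumed scaled so that n* = 1, hence the bare (1+lam) factors.
    """
    if not 0.0 < theta_star < 1.0:
        raise ValueError(f"theta_star must lie in (0,1), got {theta_star}")
    return float(
        theta_star * f_second(theta_star, params)
        - params.tau0 / (1.0 + params.lam)
        - theta_star * 2.0 * params.tau0 * N01 / (1.0 + params.lam) ** 2
    )


def _gamma_factor(theta_star: float, gamma: float, params: GelParameters) -> float:
    """Common rate factor Gamma = (1-theta*) gamma^2/(xi theta*) + 1/R."""
    return (1.0 - theta_star) * gamma**2 / (params.xi * theta_star) + 1.0 / params.R


def perturbation_growth_factor(
    which: str,
    T_hat,
    spec: PerturbationSpec,
    theta_star: float,
    params: GelParameters,
):
    """Amplitude multiplier of the cosine mode at short time T = delta*T_hat.

    For ``which = "theta"`` or ``"h"`` the multiplier is
        1 - z * c * delta*T_hat * Gamma           (c = theta* resp. 1/(2 H01)),
    and for ``"n"`` it is
        1 - delta*T_hat * (D gamma^2 + z Gamma / N01),
    with Gamma = (1-theta*) gamma^2/(xi theta*) + 1/R.  The diffusion term
    enters the cell mode with a *damping* sign: it comes from
    D d^2/dX^2 [N01 cos(gamma X)] = -D gamma^2 N01 cos(gamma X) in the
    short-time cell balance, so diffusion always shrinks the cell mode.
    """
    z = z_statistic(theta_star, spec.N01, params)
    gam = spec.gamma
    Gamma = _gamma_factor(theta_star, gam, params)
    dT = spec.delta * np.asarray(T_hat, dtype=float)
    if which == "theta":
        return 1.0 - z * theta_star * dT * Gamma
    if which == "h":
        return 1.0 - z * dT * Gamma / (2.0 * spec.H01)
    if which == "n":
        return 1.0 - dT * (params.D * gam**2 + z * Gamma / spec.N01)
    raise ValueError(f"unknown variable {which!r}")


def small_time_solution(
    X,
    T_hat: float,
    spec: PerturbationSpec,
    theta_star: float,
    params: GelParameters,
) -> dict:
    """Closed-form short-time profiles of the perturbed equilibrium.

    Evaluates, at T = delta*T_hat and to O(delta),

        theta_p = theta* + A_theta(T_hat) eps cos(gamma X)
        n       = 1     + A_n(T_hat) eps N01 cos(gamma X)
        h       = 1     - A_h(T_hat) eps H01 cos(gamma X)
        L       = 1
        v_p     = delta-independent seed velocity
                  [(1-theta*) gamma/(2 xi theta*) + 1/(2 R gamma)] z sin(gamma X)

    where the A(T_hat) are the growth factors of
    :func:`perturbation_growth_factor`.  At T_hat = 0 this is exactly the
    perturbed initial condition.  Returns a dict with keys
    ``theta_p, n, h, L, v_p``.
    """
    if not 0.0 < theta_star < 1.0:
        raise ValueError(f"theta_star must lie in (0,1), got {theta_star}")
    X = np.asarray(X, dtype=float)
    gam = spec.gamma
    cos = np.cos(gam * X)
    z = z_statistic(theta_star, spec.N01, params)
    v01 = (
        (1.0 - theta_star) * gam / (2.0 * params.xi * theta_star)
        + 1.0 / (2.0 * params.R * gam)
    ) * z * np.sin(gam * X)
    return {
        "theta_p": theta_star
        + perturbation_growth_factor("theta", T_hat, spec, theta_star, params)
        * spec.eps * cos,
        "n": 1.0
        + perturbation_growth_factor("n", T_hat, spec, theta_star, params)
        * spec.eps * spec.N01 * cos,
        "h": 1.0
        - perturbation_growth_factor("h", T_hat, spec, theta_star, params)
        * spec.eps * spec.H01 * cos,
        "L": 1.0,
        "v_p": spec.eps * v01,
    }


def stability_report(
    theta_star: float, spec: PerturbationSpec, params: GelParameters
) -> StabilityReport:
    """Growth/decay verdicts for each perturbed variable.

    The theta_p/h modes decay iff z > 0.  The cell mode decays iff
    D gamma^2 + z Gamma / N01 > 0 (diffusion damps; see
    :func:`perturbation_growth_factor`).
    """
    z = z_statistic(theta_star, spec.N01, params)
    Gamma = _gamma_factor(theta_star, spec.gamma, params)
    rate_th = -z * Gamma  # sign of d(amplitude)/dT for the theta/h modes
    rate_n = -(params.D * spec.gamma**2 + z * Gamma / spec.N01)
    return StabilityReport(
        theta_star=theta_star,
        z=z,
        growth_rate_theta_h=rate_th,
        growth_rate_n=rate_n,
        verdict_theta_h="decaying" if z > 0 else "growing",
        verdict_n="decaying" if rate_n < 0 else "growing",
    )
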