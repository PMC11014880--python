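"""Reduced model for spatially uniform films: a single ODE for the height.

A film that starts spatially uniform stays uniform for all time, and the
whole thin-film system collapses to one stiff ODE for the scaled
half-height h(t) (h(0) = 1):

    dh/dt = -(1/(2R)) * [ mu_s(theta_p) - mu_s^e + theta_p G(n) ],

with every other variable slaved to h through exact mass conservation:

    theta_p = theta_I / h^2,   n = n_I / h^2,   L = h,
    v_p(x, t) = (x/h) dh/dt.

Time enters only through t/R, so doubling the interface resistance R
exactly halves the rate of approach to equilibrium without changing the
equilibrium itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .potentials import GelParameters, equilibrium_residual

__all__ = [
    "UniformState",
    "UniformTrajectory",
    "height_rate",
    "integrate_uniform",
    "time_to_equilibrium",
]

#: |dh/dt| below which the film is declared at equilibrium.
EQUILIBRIUM_RATE_TOL = 1e-10

#: keep theta_p = theta_I/h^2 at least this far inside (0, 1)
_THETA_MARGIN = 1e-9


@dataclass(frozen=True)
class UniformState:
    """A spatially uniform film at one instant."""

    t: float
    h: float
    theta_p: float
    n: float
    L: float

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ValueError(f"h must be > 0, got {self.h}")
        if not 0.0 < self.theta_p < 1.0:
            raise ValueError(f"theta_p must lie in (0,1), got {self.theta_p}")


@dataclass
class UniformTrajectory:
    """Time series of a uniform film plus terminal diagnostics.

    ``flag`` is one of ``"converged"`` (reached equilibrium to within
    :data:`EQUILIBRIUM_RATE_TOL`), ``"max-time"`` or ``"invalid-theta"``
    (theta_p = theta_I/h^2 left (0,1): the model broke down).
    """

    t: np.ndarray
    h: np.ndarray
    theta_I: float
    n_I: float
    params: GelParameters
    flag: str
    _dense = None  # scipy OdeSolution for interpolation

    @property
    def theta_p(self) -> np.ndarray:
        return self.theta_I / self.h**2

    @property
    def n(self) -> np.ndarray:
        return self.n_I / self.h**2

    @property
    def L(self) -> np.ndarray:
        return self.h

    @property
    def converged(self) -> bool:
        return self.flag == "converged"

    def state(self, i: int) -> UniformState:
        return UniformState(
            t=float(self.t[i]),
            h=float(self.h[i]),
            theta_p=float(self.theta_p[i]),
            n=float(self.n[i]),
            L=float(self.h[i]),
        )

    @property
    def terminal(self) -> UniformState:
        return self.state(len(self.t) - 1)

    @property
    def equilibrium(self) -> Optional[UniformState]:
        """Terminal state, if the trajectory converged; else None."""
        return self.terminal if self.converged else None

    def h_at(self, t) -> np.ndarray:
        """Interpolated h(t): dense solver output inside the integration
        window, the terminal (equilibrium) value beyond it."""
        t = np.asarray(t, dtype=float)
        tc = np.clip(t, self.t[0], self.t[-1])
        if self._dense is not None:
            return np.atleast_1d(self._dense(tc))[0] if tc.ndim == 0 else self._dense(tc)[0]
        return np.interp(tc, self.t, self.h)

    def summary(self) -> dict:
        """JSON-ready terminal summary (values also rounded to 2 d.p. in
        the style the equilibria are usually reported)."""
        term = self.terminal
        out = {
            "flag": self.flag,
            "t_end": term.t,
            "h": term.h,
            "theta_p": term.theta_p,
            "n": term.n,
            "L": term.L,
        }
        if self.converged:
            out["equilibrium_2dp"] = {
                "theta_star": round(term.theta_p, 2),
                "n_star": round(term.n, 2),
                "h_star": round(term.h, 2),
                "L_star": round(term.L, 2),
            }
        return out

    def to_csv(self, path) -> None:
        data = np.column_stack([self.t, self.h, self.theta_p, self.n, self.L])
        np.savetxt(
            path, data, delimiter=",", header="t,h,theta_p,n,L", comments="",
            fmt="%.12g",
        )


def height_rate(h, theta_I: float, n_I: float, params: GelParameters):
    """dh/dt of the uniform film at height h (theta_I, n_I at h=1).

    Linear in 1/R; vanishes exactly at roots of the equilibrium residual.
    Raises ValueError when theta_I/h^2 leaves (0, 1).
    """
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError(f"h must be > 0, got {h!r}")
    theta = theta_I / h**2
    if np.any(theta >= 1.0) or np.any(theta <= 0.0):
        raise ValueError(
            f"invalid-theta: theta_I/h^2 = {theta!r} left (0, 1)"
        )
    n = n_I / h**2
    return -equilibrium_residual(theta, n, params) / (2.0 * params.R)


def integrate_uniform(
    theta_I: float,
    n_I: float,
    params: GelParameters,
    t_end: float = 2000.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    eq_tol: float = EQUILIBRIUM_RATE_TOL,
) -> UniformTrajectory:
    """Integrate the uniform-film height ODE with a stiff adaptive solver.

    Integration stops early at equilibrium (|dh/dt| < ``eq_tol``) or when
    theta_p = theta_I/h^2 approaches the ends of (0, 1) (model breakdown).
    Non-convergence within ``t_end`` is reported through the trajectory
    flag, not raised.
    """
    if not 0.0 < theta_I < 1.0:
        raise ValueError(f"theta_I must lie in (0,1), got {theta_I}")
    if n_I < 0:
        raise ValueError(f"n_I must be >= 0, got {n_I}")

    def rhs(t, y):
        return [height_rate(y[0], theta_I, n_I, params)]

    def ev_equilibrium(t, y):
        return abs(rhs(t, y)[0]) - eq_tol

    ev_equilibrium.terminal = True
    ev_equilibrium.direction = -1

    # theta_I/h^2 hits 1 - margin when h falls to this floor
    h_floor = np.sqrt(theta_I / (1.0 - _THETA_MARGIN))

    def ev_breakdown(t, y):
        return y[0] - h_floor

    ev_breakdown.terminal = True
    ev_breakdown.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [1.0],
        method="LSODA",
        rtol=rtol,
        atol=atol,
        dense_output=True,
        events=[ev_equilibrium, ev_breakdown],
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")

    if sol.t_events[1].size:
        flag = "invalid-theta"
    elif sol.t_events[0].size:
        flag = "converged"
    else:
        # may still be at equilibrium if the initial state already was
        rate = height_rate(sol.y[0, -1], theta_I, n_I, params)
        flag = "converged" if abs(rate) < eq_tol else "max-time"

    traj = UniformTrajectory(
        t=sol.t, h=sol.y[0], theta_I=theta_I, n_I=n_I, params=params, flag=flag
    )
    traj._dense = sol.sol
    return traj


def time_to_equilibrium(traj: UniformTrajectory, eps_h: float) -> float:
    """First time with |h(t) - h*| < eps_h, staying within the band after.

    h* is the terminal (equilibrium) height.  Because h solves an equation
    of the form F(t/R), this time scales exactly linearly with the
    interface resistance R.  Undefined (raises) on non-converged
    trajectories.
    """
    if not traj.converged:
        raise ValueError("time_to_equilibrium requires a converged trajectory")
    h_star = traj.terminal.h
    # fine sampling of the dense solution for a sharp entry time
    ts = np.linspace(traj.t[0], traj.t[-1], 20001)
    hs = traj.h_at(ts)
    inside = np.abs(hs - h_star) < eps_h
    if inside.all():
        return 0.0
    # last index outside the band; entry happens just after it
    last_out = np.max(np.nonzero(~inside))
    if last_out == len(ts) - 1:
        raise ValueError("trajectory never settles inside the eps_h band")
    # bisect the bracketing interval for the crossing
    lo, hi = ts[last_out], ts[last_out + 1]
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if abs(float(traj.h_at(mid)) - h_star) < eps_h:
            hi = mid
        else:
            lo = mid
    return float(hi)
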