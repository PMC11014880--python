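"""Thermodynamic and cell-force potentials of the two-phase gel.

The gel is a mixture of polymer (volume fraction ``theta_p``) and solvent
(``theta_s = 1 - theta_p``) carrying a cell population of density ``n``.
Mixing thermodynamics follow Flory–Huggins theory: the dimensionless free
energy density of the mixture is

    f(theta_p) = (theta_p/N) log theta_p + theta_s log theta_s
                 + chi theta_p theta_s + mu_p0 theta_p + mu_s0 theta_s,

where ``N`` is the polymer chain length, ``chi`` the Flory interaction
parameter and ``mu_p0``, ``mu_s0`` the standard free energies.  All
quantities are dimensionless (the k_B*T/nu_m prefactor is scaled to one).
Chemical potentials derive from ``f`` in the usual two-phase way,

    mu_p = f + theta_s f',      mu_s = f - theta_p f',

and cells pull on the polymer network through the saturating traction
potential ``G(n) = tau0 n^2 / (1 + lam n^2)`` (``lam`` models contact
inhibition).  Everything here is a pure function of state; the solvers in
:mod:`gelfilm.uniform` and :mod:`gelfilm.solver` build on these.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GelParameters",
    "free_energy",
    "mu_s",
    "mu_p",
    "f_prime",
    "f_second",
    "cell_potential",
    "cell_potential_deriv",
    "equilibrium_residual",
]


@dataclass(frozen=True)
class GelParameters:
    """Dimensionless constants of the gel model.

    Defaults are the values held fixed across all baseline simulations:
    ``N=100``, ``lam=1``, ``mu_p0=mu_s0=0``, ``tau0=1``.  ``chi``, ``xi``,
    ``R`` and ``D`` are the dials that distinguish scenarios.  The bulk
    viscosities of both phases cancel from the leading-order thin-film
    system (and are zero in the baseline anyway), so they are not stored.

    Attributes
    ----------
    N : polymer chain length (>= 1).
    chi : Flory interaction parameter; larger chi favours demixing
        (contraction), smaller chi favours mixing (swelling).
    mu_p0, mu_s0 : standard free energies of pure polymer / pure solvent.
    tau0 : cell traction coefficient (>= 0).
    lam : contact inhibition parameter (>= 0).
    xi : polymer–solvent drag coefficient (> 0).
    R : resistance of the gel–solvent interface to transboundary flow (> 0).
    D : cell diffusion coefficient (>= 0).
    """

    N: float = 100.0
    chi: float = 0.75
    mu_p0: float = 0.0
    mu_s0: float = 0.0
    tau0: float = 1.0
    lam: float = 1.0
    xi: float = 1.0
    R: float = 1.0
    D: float = 1.0

    def __post_init__(self) -> None:
        if not self.N >= 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if not np.isfinite(self.chi):
            raise ValueError(f"chi must be finite, got {self.chi}")
        if not self.xi > 0:
            raise ValueError(f"xi must be > 0, got {self.xi}")
        if not self.R > 0:
            raise ValueError(f"R must be > 0, got {self.R}")
        if not self.tau0 >= 0:
            raise ValueError(f"tau0 must be >= 0, got {self.tau0}")
        if not self.lam >= 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if not self.D >= 0:
            raise ValueError(f"D must be >= 0, got {self.D}")

    @property
    def mu_s_ext(self) -> float:
        """External (pure solvent) chemical potential, mu_s^e = f(0) = mu_s0."""
        return self.mu_s0

    def with_(self, **kwargs) -> "GelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _check_theta(theta_p, allow_boundary: bool) -> np.ndarray:
    th = np.asarray(theta_p, dtype=float)
    lo, hi = (0.0, 1.0)
    if allow_boundary:
        ok = (th >= lo) & (th <= hi)
    else:
        ok = (th > lo) & (th < hi)
    if not np.all(ok):
        bad = th[~np.atleast_1d(ok)] if th.ndim else th
        raise ValueError(
            f"theta_p must lie in the open interval (0, 1); got {bad!r}"
        )
    return th


def _xlogx(x: np.ndarray) -> np.ndarray:
    """x*log(x) with the continuous limit 0 at x=0."""
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def free_energy(theta_p, params: GelParameters, *, allow_boundary: bool = False):
    """Flory–Huggins free energy density f(theta_p) of the mixture.

    With ``allow_boundary=True`` the finite limits at theta_p = 0 or 1 are
    returned using the x*log(x) -> 0 convention; otherwise the open
    interval (0, 1) is enforced.
    """
    th = _check_theta(theta_p, allow_boundary)
    th = np.atleast_1d(th)
    ts = 1.0 - th
    f = (
        _xlogx(th) / params.N
        + _xlogx(ts)
        + params.chi * th * ts
        + params.mu_p0 * th
        + params.mu_s0 * ts
    )
    return f if np.ndim(theta_p) else float(f[0])


def f_prime(theta_p, params: GelParameters):
    """First derivative f'(theta_p) of the free energy."""
    th = _check_theta(theta_p, False)
    return (
        (np.log(th) + 1.0) / params.N
        - np.log(1.0 - th)
        - 1.0
        + params.chi * (1.0 - 2.0 * th)
        + params.mu_p0
        - params.mu_s0
    )


def f_second(theta_p, params: GelParameters):
    """Second derivative f''(theta_p) = 1/(N theta_p) + 1/(1-theta_p) - 2 chi.

    Positive f'' everywhere signals a thermodynamically stable mixture
    (guaranteed for chi <= 1/2, N >= 1); where f'' < 0 the osmotic response
    is destabilising.
    """
    th = _check_theta(theta_p, False)
    return 1.0 / (params.N * th) + 1.0 / (1.0 - th) - 2.0 * params.chi


def mu_s(theta_p, params: GelParameters, *, allow_boundary: bool = False):
    """Solvent chemical potential mu_s = f - theta_p f'.

    Closed form: log(1 - theta_p) + (1 - 1/N) theta_p + chi theta_p^2 + mu_s0.
    Gradients of mu_s drive solvent flow within the gel; the jump
    mu_s - mu_s^e across the free surface drives trans-boundary flux.
    The theta_p -> 0 limit (pure solvent) equals mu_s0 and is returned under
    ``allow_boundary=True``; the theta_p -> 1 limit diverges and is always
    rejected.
    """
    th = np.asarray(theta_p, dtype=float)
    if allow_boundary:
        if np.any(th >= 1.0) or np.any(th < 0.0):
            raise ValueError("mu_s requires theta_p in [0, 1)")
    else:
        _check_theta(theta_p, False)
    return (
        np.log(1.0 - th)
        + (1.0 - 1.0 / params.N) * th
        + params.chi * th**2
        + params.mu_s0
    )


def mu_p(theta_p, params: GelParameters, *, allow_boundary: bool = False):
    """Polymer chemical potential mu_p = f + theta_s f'.

    Closed form: (log theta_p + 1 - theta_p)/N + theta_p
    + chi (1-theta_p)^2 - 1 + mu_p0 ... expanded below.  The theta_p -> 1
    limit (pure polymer) is finite and equals mu_p0 + (1 - 1/... ) terms;
    it is returned under ``allow_boundary=True``.  theta_p -> 0 diverges.
    """
    th = np.asarray(theta_p, dtype=float)
    if allow_boundary:
        if np.any(th <= 0.0) or np.any(th > 1.0):
            raise ValueError("mu_p requires theta_p in (0, 1]")
    else:
        _check_theta(theta_p, False)
    ts = 1.0 - th
    return (
        (np.log(th) + ts) / params.N
        - ts
        + params.chi * ts**2
        + params.mu_p0
    )


def cell_potential(n, params: GelParameters):
    """Cell traction potential G(n) = tau0 n^2 / (1 + lam n^2).

    G saturates at tau0/lam for large n (contact inhibition); its gradient
    is the force cells exert on the polymer network, directed up gradients
    of cell density since G'(n) > 0 for n > 0.
    """
    narr = np.asarray(n, dtype=float)
    if np.any(narr < 0):
        raise ValueError(f"cell density n must be >= 0, got {n!r}")
    return params.tau0 * narr**2 / (1.0 + params.lam * narr**2)


def cell_potential_deriv(n, params: GelParameters):
    """G'(n) = 2 tau0 n / (1 + lam n^2)^2; strictly positive for n, tau0 > 0."""
    narr = np.asarray(n, dtype=float)
    if np.any(narr < 0):
        raise ValueError(f"cell density n must be >= 0, got {n!r}")
    return 2.0 * params.tau0 * narr / (1.0 + params.lam * narr**2) ** 2


def equilibrium_residual(theta_p, n, params: GelParameters):
    """Force balance across the gel surface: mu_s - mu_s^e + theta_p G(n).

    Zero residual is the necessary and sufficient condition for a steady
    state of the thin-film model (with spatially uniform theta_p and n).
    Positive residual drives solvent out of the gel (contraction), negative
    residual draws solvent in (swelling).  theta_p -> 0 is the trivial
    fully-dissolved root; root finders must exclude it.
    """
    return (
        mu_s(theta_p, params)
        - params.mu_s_ext
        + np.asarray(theta_p, dtype=float) * cell_potential(n, params)
    )
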