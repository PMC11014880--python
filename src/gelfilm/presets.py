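"""Programmatic initial conditions and the named scenario presets.

Every simulation in the package starts from either a spatially uniform
film or one perturbed by a single cosine mode,

    f(X) = mean + a * cos(Z pi X),

which satisfies the symmetry/no-flux conditions df/dX = 0 at X = 0 and
X = 1 for any integer mode Z >= 1.  Initial height and cell density are
normalised to unit spatial mean (that is how the model is scaled: the
height and cell-density scales are the average initial values), while the
polymer fraction keeps its prescribed mean.

The ``preset`` registry reproduces the published scenario table: a
cell-free swelling film (chi = 0.75), a demixing contracting film
(chi = 1.5), cell-seeded films with strong/weak traction, the resistance
sweep, the non-uniform-initial-condition runs, the drag and resistance
comparisons, and the zero-diffusion run (chi = 0.4, D = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Dict, Tuple

import numpy as np

from .potentials import GelParameters
from .solver import FilmState

__all__ = [
    "InitialConditionSpec",
    "make_initial_state",
    "preset",
    "preset_names",
]


@dataclass(frozen=True)
class InitialConditionSpec:
    """Uniform or single-cosine-mode initial film profiles.

    ``theta_mean`` is the spatial mean polymer fraction; ``n_mean`` must be
    0 (cell-free) or 1 (cell-seeded, in units of the mean initial density);
    the height profile is rescaled to unit mean.  Amplitudes of zero give a
    uniform film.
    """

    theta_mean: float = 0.6
    theta_amp: float = 0.0
    n_mean: float = 0.0
    n_amp: float = 0.0
    h_amp: float = 0.0
    Z: int = 1

    def __post_init__(self) -> None:
        if not (isinstance(self.Z, (int, np.integer)) and self.Z >= 1):
            raise ValueError(f"mode Z must be a positive integer, got {self.Z}")
        if self.n_mean not in (0.0, 1.0, 0, 1):
            raise ValueError(
                f"n_mean must be 0 (cell-free) or 1 (scaled), got {self.n_mean}"
            )
        if not 0.0 < self.theta_mean < 1.0:
            raise ValueError(
                f"theta_mean must lie in (0,1), got {self.theta_mean}"
            )
        if not (0.0 < self.theta_mean - abs(self.theta_amp)
                and self.theta_mean + abs(self.theta_amp) < 1.0):
            raise ValueError(
                "theta profile leaves (0,1): mean "
                f"{self.theta_mean} with amplitude {self.theta_amp}"
            )
        if self.n_mean - abs(self.n_amp) < 0.0:
            raise ValueError(
                f"n profile goes negative: mean {self.n_mean} with "
                f"amplitude {self.n_amp}"
            )
        if abs(self.h_amp) >= 1.0:
            raise ValueError(
                f"h profile must stay positive: amplitude {self.h_amp}"
            )

    @property
    def uniform(self) -> bool:
        return self.theta_amp == self.n_amp == self.h_amp == 0.0

    def profiles(self, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(theta_I, n_I, h_I) on the grid, with h normalised to unit mean.

        A cosine mode has zero integral over [0, 1], so the continuous mean
        of each profile already equals the prescribed value; the height is
        nevertheless rescaled by its own integral so that the unit-mean
        normalisation holds exactly however the profile was built.
        """
        cos = np.cos(self.Z * math.pi * X)
        theta_I = self.theta_mean + self.theta_amp * cos
        n_I = self.n_mean + self.n_amp * cos
        h_I = 1.0 + self.h_amp * cos
        h_I = h_I / np.trapezoid(h_I, X)  # continuous mean is 1 by construction
        return theta_I, n_I, h_I

    def to_dict(self) -> dict:
        return asdict(self)


def make_initial_state(spec: InitialConditionSpec, grid: np.ndarray) -> FilmState:
    """FilmState at T = 0 from an initial-condition spec.

    Q = theta_I * h_I and W = (1 - theta_I) * h_I; the velocity is left
    unset (the solver computes it before the first step).  L(0) = 1.
    """
    theta_I, n_I, h_I = spec.profiles(np.asarray(grid, dtype=float))
    if np.any(theta_I <= 0) or np.any(theta_I >= 1):
        raise ValueError("theta_I leaves (0,1) on the grid")
    if np.any(h_I <= 0):
        raise ValueError("h_I must be positive on the grid")
    if np.any(n_I < 0):
        raise ValueError("n_I must be nonnegative on the grid")
    return FilmState(
        X=np.asarray(grid, dtype=float),
        Q=theta_I * h_I,
        W=(1.0 - theta_I) * h_I,
        n=n_I,
        L=1.0,
        T=0.0,
        v_p=None,
    )


_COS = {"theta_amp": 0.02}  # the published perturbation amplitude, mode Z=1

_PRESETS: Dict[str, Tuple[GelParameters, InitialConditionSpec]] = {
    # uniform films, reduced-ODE scenarios
    "fig2a": (GelParameters(chi=0.75, D=0.0),
              InitialConditionSpec(theta_mean=0.6, n_mean=0.0)),
    "fig2b": (GelParameters(chi=1.5, D=0.0),
              InitialConditionSpec(theta_mean=0.6, n_mean=0.0)),
    "fig3a": (GelParameters(chi=0.75, tau0=1.0, D=1.0),
              InitialConditionSpec(theta_mean=0.6, n_mean=1.0)),
    "fig3b": (GelParameters(chi=0.75, tau0=0.1, D=1.0),
              InitialConditionSpec(theta_mean=0.6, n_mean=1.0)),
    "fig3c_R5": (GelParameters(chi=0.75, tau0=1.0, R=5.0, D=1.0),
                 InitialConditionSpec(theta_mean=0.6, n_mean=1.0)),
    # spatially varying runs, full PDE
    "fig4": (GelParameters(chi=0.75, xi=1.0, R=1.0, D=0.0),
             InitialConditionSpec(theta_mean=0.6, theta_amp=0.02, n_mean=0.0)),
    "fig5": (GelParameters(chi=0.75, xi=1.0, R=1.0, tau0=1.0, D=1.0),
             InitialConditionSpec(theta_mean=0.6, theta_amp=0.02, n_mean=1.0)),
    "fig6": (GelParameters(chi=0.75, xi=1.0, R=1.0, tau0=1.0, D=1.0),
             InitialConditionSpec(theta_mean=0.6, n_mean=1.0, n_amp=0.02)),
    "fig7_high_drag": (GelParameters(chi=0.75, xi=4.0, R=1.0, tau0=1.0, D=1.0),
                       InitialConditionSpec(theta_mean=0.6, theta_amp=0.02,
                                            n_mean=1.0)),
    "fig7_low_drag": (GelParameters(chi=0.75, xi=0.2, R=1.0, tau0=1.0, D=1.0),
                      InitialConditionSpec(theta_mean=0.6, theta_amp=0.02,
                                           n_mean=1.0)),
    "fig8_highR": (GelParameters(chi=0.75, xi=1.0, R=4.0, tau0=1.0, D=1.0),
                   InitialConditionSpec(theta_mean=0.6, theta_amp=0.02,
                                        n_mean=1.0)),
    "fig8_lowR": (GelParameters(chi=0.75, xi=1.0, R=0.4, tau0=1.0, D=1.0),
                  InitialConditionSpec(theta_mean=0.6, theta_amp=0.02,
                                       n_mean=1.0)),
    "fig9_zeroD": (GelParameters(chi=0.4, xi=1.0, R=1.0, tau0=1.0, D=0.0),
                   InitialConditionSpec(theta_mean=0.6, n_mean=1.0,
                                        n_amp=0.02)),
}


def preset(name: str) -> Tuple[GelParameters, InitialConditionSpec]:
    """Parameter set and initial condition of a named published scenario."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; known: {', '.join(sorted(_PRESETS))}"
        ) from None


def preset_names() -> tuple:
    return tuple(sorted(_PRESETS))
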