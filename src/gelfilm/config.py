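"""JSON run configuration, dispatch, and on-disk artifacts.

A run is described by a small JSON document::

    {
      "mode": "simulate" | "uniform" | "equilibria" | "stability",
      "params":  {"N": 100, "chi": 0.75, "mu_p0": 0, "mu_s0": 0,
                  "tau0": 1, "lam": 1, "xi": 1, "R": 1, "D": 1},
      "initial": {"theta_mean": 0.6, "theta_amp": 0.02,
                  "n_mean": 1, "n_amp": 0, "h_amp": 0, "Z": 1},
      "grid":    {"M": 41, "dT": 1e-4, "T_end": 8.0,
                  "snapshot_times": [0.1, 0.5, 1.0]},
      "ode":     {"t_end": 100.0, "rtol": 1e-8, "atol": 1e-10},
      "stability": {"Z": 1, "eps": 0.01, "delta": 0.001,
                    "N01": 1.0, "H01": 1.0, "T_hat": 1.0},
      "allow_zero_diffusion": false
    }

Only ``mode`` and ``params.chi`` are required; everything else defaults to
the baseline scenario values.  Validation reports the offending field by
its dotted path.  Outputs land in a run directory: per-snapshot CSV files
(``simulate``), a ``summary.json``, a plain-text log with the mass-drift
series, and a ``manifest.json`` recording the config hash and settings.
Identical configurations reproduce byte-identical CSV and summary files
(the model has no randomness); the manifest additionally records
wall-clock times and is the one artifact exempt from that guarantee.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .equilibria import (
    PerturbationSpec,
    find_equilibria,
    small_time_solution,
    stability_report,
)
from .potentials import GelParameters
from .presets import InitialConditionSpec, make_initial_state, preset
from .solver import BreakdownError, advance, make_grid
from .uniform import integrate_uniform

__all__ = ["ConfigError", "load_config", "run_from_config", "report_equilibrium",
           "preset_config"]

_MODES = ("simulate", "uniform", "equilibria", "stability")

_PARAM_FIELDS = {
    "N": 100.0, "chi": None, "mu_p0": 0.0, "mu_s0": 0.0, "tau0": 1.0,
    "lam": 1.0, "xi": 1.0, "R": 1.0, "D": 1.0,
}
_INITIAL_FIELDS = {
    "theta_mean": 0.6, "theta_amp": 0.0, "n_mean": 0.0, "n_amp": 0.0,
    "h_amp": 0.0, "Z": 1,
}
_GRID_FIELDS = {"M": 41, "dT": 1e-4, "T_end": 8.0, "snapshot_times": []}
_ODE_FIELDS = {"t_end": 2000.0, "rtol": 1e-8, "atol": 1e-10}
_STAB_FIELDS = {"Z": 1, "eps": 0.01, "delta": 1e-3, "N01": 1.0, "H01": 1.0,
                "T_hat": 1.0}


class ConfigError(ValueError):
    """A configuration document failed validation; the message names the
    offending field by its dotted path."""


def _take(section: dict, defaults: dict, path: str) -> dict:
    out = {}
    unknown = set(section) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown field(s) {sorted(unknown)} in '{path}'")
    for key, default in defaults.items():
        val = section.get(key, default)
        if val is None:
            raise ConfigError(f"required field '{path}.{key}' is missing")
        out[key] = val
    return out


def load_config(path) -> dict:
    """Read and validate a configuration file; returns the resolved dict."""
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config is not valid JSON: {exc}") from exc
    return validate_config(raw)


def validate_config(raw: dict) -> dict:
    if not isinstance(raw, dict):
        raise ConfigError("config must be a JSON object")
    mode = raw.get("mode")
    if mode not in _MODES:
        raise ConfigError(f"'mode' must be one of {_MODES}, got {mode!r}")
    cfg = {
        "mode": mode,
        "params": _take(raw.get("params", {}), _PARAM_FIELDS, "params"),
        "initial": _take(raw.get("initial", {}), _INITIAL_FIELDS, "initial"),
        "grid": _take(raw.get("grid", {}), _GRID_FIELDS, "grid"),
        "ode": _take(raw.get("ode", {}), _ODE_FIELDS, "ode"),
        "stability": _take(raw.get("stability", {}), _STAB_FIELDS, "stability"),
        "allow_zero_diffusion": bool(raw.get("allow_zero_diffusion", False)),
    }
    # constructor invariants re-raised with their field paths
    try:
        params = GelParameters(**cfg["params"])
    except ValueError as exc:
        name = str(exc).split()[0]
        raise ConfigError(f"params.{name}: {exc}") from exc
    try:
        init = InitialConditionSpec(**cfg["initial"])
    except ValueError as exc:
        raise ConfigError(f"initial: {exc}") from exc
    if not cfg["grid"]["M"] >= 5:
        raise ConfigError(f"grid.M must be >= 5, got {cfg['grid']['M']}")
    if not cfg["grid"]["dT"] > 0:
        raise ConfigError(f"grid.dT must be > 0, got {cfg['grid']['dT']}")
    if not cfg["grid"]["T_end"] > 0:
        raise ConfigError(f"grid.T_end must be > 0, got {cfg['grid']['T_end']}")
    cfg["_params"] = params
    cfg["_initial"] = init
    return cfg


def preset_config(name: str, mode: str = "simulate", **grid_overrides) -> dict:
    """JSON-ready config document for a named preset scenario."""
    params, init = preset(name)
    grid = dict(_GRID_FIELDS)
    grid["snapshot_times"] = list(grid["snapshot_times"])
    grid.update(grid_overrides)
    return {
        "mode": mode,
        "params": {k: getattr(params, k) for k in _PARAM_FIELDS},
        "initial": init.to_dict(),
        "grid": grid,
        "allow_zero_diffusion": bool(params.D == 0.0 and init.n_mean > 0),
    }


def _config_hash(cfg: dict) -> str:
    public = {k: v for k, v in cfg.items() if not k.startswith("_")}
    blob = json.dumps(public, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _snapshot_csv(path: Path, state) -> None:
    data = np.column_stack([
        state.X, state.Q, state.W, state.h, state.theta_p, state.n,
        state.v_p if state.v_p is not None else np.zeros_like(state.X),
    ])
    np.savetxt(path, data, delimiter=",",
               header="X,Q,W,h,theta_p,n,v_p", comments="", fmt="%.12g")


def run_from_config(
    path,
    out_dir,
    dT: Optional[float] = None,
    dX: Optional[float] = None,
    T_end: Optional[float] = None,
) -> dict:
    """Execute the run a config file describes; returns the summary dict.

    Artifacts (CSV series, ``summary.json``, ``log.txt``,
    ``manifest.json``) are written under ``out_dir``.  Solver breakdown
    writes a state dump and re-raises.
    """
    cfg = load_config(path)
    if dT is not None:
        cfg["grid"]["dT"] = dT
    if dX is not None:
        cfg["grid"]["M"] = int(round(1.0 / dX)) + 1
    if T_end is not None:
        cfg["grid"]["T_end"] = T_end

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    params: GelParameters = cfg["_params"]
    init: InitialConditionSpec = cfg["_initial"]
    mode = cfg["mode"]
    log_lines = [f"gelfilm {__version__} mode={mode}"]

    if mode == "uniform":
        traj = integrate_uniform(
            init.theta_mean, init.n_mean, params,
            t_end=cfg["ode"]["t_end"], rtol=cfg["ode"]["rtol"],
            atol=cfg["ode"]["atol"],
        )
        traj.to_csv(out / "trajectory.csv")
        summary = traj.summary()
        log_lines.append(f"flag={traj.flag} t_end={traj.t[-1]:.6g}")
    elif mode == "equilibria":
        points = find_equilibria(init.theta_mean, max(init.n_mean, 0.0), params)
        summary = {
            "equilibria": [
                {
                    "theta_star": p.theta_star,
                    "n_star": p.n_star,
                    "h_star": p.h_star,
                    "L_star": p.L_star,
                    "residual_at_root": p.residual_at_root,
                }
                for p in points
            ],
            "count": len(points),
        }
        log_lines.append(f"interior roots: {len(points)}")
    elif mode == "stability":
        st = cfg["stability"]
        spec = PerturbationSpec(Z=int(st["Z"]), eps=st["eps"],
                                delta=st["delta"], N01=st["N01"],
                                H01=st["H01"])
        points = find_equilibria(init.theta_mean, max(init.n_mean, 0.0), params)
        if not points:
            raise ConfigError(
                "stability mode needs an interior equilibrium for "
                "initial.theta_mean but none was found"
            )
        theta_star = points[0].theta_star
        report = stability_report(theta_star, spec, params)
        X = make_grid(cfg["grid"]["M"])
        prof = small_time_solution(X, st["T_hat"], spec, theta_star, params)
        data = np.column_stack([X, prof["theta_p"], prof["n"], prof["h"],
                                prof["v_p"]])
        np.savetxt(out / "small_time_profiles.csv", data, delimiter=",",
                   header="X,theta_p,n,h,v_p", comments="", fmt="%.12g")
        summary = report.to_dict()
        log_lines.append(f"z={report.z:.6g}")
    else:  # simulate
        grid = make_grid(cfg["grid"]["M"])
        state0 = make_initial_state(init, grid)
        try:
            result = advance(
                state0, params,
                T_end=cfg["grid"]["T_end"], dT=cfg["grid"]["dT"],
                snapshot_times=cfg["grid"]["snapshot_times"],
                allow_zero_diffusion=cfg["allow_zero_diffusion"],
            )
        except BreakdownError as exc:
            if exc.state is not None:
                _snapshot_csv(out / "state_dump.csv", exc.state)
                log_lines.append(f"BREAKDOWN at T={exc.state.T:g}: {exc}")
                (out / "log.txt").write_text("\n".join(log_lines) + "\n")
            raise
        for i, snap in enumerate(result.snapshots):
            _snapshot_csv(out / f"snapshot_{i:03d}.csv", snap)
        summary = result.summary()
        summary["snapshot_times"] = [s.T for s in result.snapshots]
        for t, mp, mc in zip(result.audit_times, result.mass_polymer,
                             result.mass_cells):
            drift_p = abs(mp - result.mass_polymer[0]) / result.mass_polymer[0]
            drift_c = (abs(mc - result.mass_cells[0]) / result.mass_cells[0]
                       if result.mass_cells[0] > 0 else 0.0)
            log_lines.append(
                f"audit T={t:.6g} polymer_drift={drift_p:.3e} "
                f"cell_drift={drift_c:.3e}"
            )

    _write_json(out / "summary.json", summary)
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    manifest = {
        "config_sha256": _config_hash(cfg),
        "code_version": __version__,
        "mode": mode,
        "grid": cfg["grid"],
        "wall_time_start": t_start,
        "wall_time_end": time.time(),
        "flags": {"converged": summary.get("converged",
                                           summary.get("flag") == "converged")},
    }
    _write_json(out / "manifest.json", manifest)
    return summary


def report_equilibrium(summary: dict) -> str:
    """Human-readable equilibrium table from a run summary.

    Columns: theta*, n*, mean h*, A_h*, L*.  Cell-free runs render n* as
    an em dash; non-converged runs are flagged and carry no equilibrium
    values.
    """
    header = f"{'theta*':>8} {'n*':>8} {'mean h*':>8} {'A_h*':>8} {'L*':>8}"
    converged = summary.get("converged", summary.get("flag") == "converged")
    if not converged:
        return header + "\n" + " (run not converged: no equilibrium values)"
    if "theta_mean" in summary:  # PDE summary
        theta, n_mean = summary["theta_mean"], summary["n_mean"]
        h_mean, amp_h = summary["h_mean"], summary["amplitude_h"]
        L = summary["L"]
    else:  # uniform-ODE summary
        theta, n_mean = summary["theta_p"], summary["n"]
        h_mean, amp_h, L = summary["h"], 0.0, summary["L"]
    n_cell = f"{n_mean:8.2f}" if n_mean > 0 else f"{'—':>8}"
    row = f"{theta:8.2f} {n_cell} {h_mean:8.2f} {amp_h:8.3f} {L:8.2f}"
    return header + "\n" + row
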