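# gelfilm

Mechanics of thin, free-floating two-phase gel films: osmotic swelling and
cell-induced contraction.

In a collagen gel contraction assay, cells cultured inside a thin gel disc
floating in nutrient medium pull on the polymer network and shrink the
gel; how much it shrinks measures the traction the cells exert.  `gelfilm`
implements a depth-averaged (thin-film/lubrication) continuum model of
this experiment.  The gel is a mixture of viscous polymer (volume fraction
θ_p) and inviscid solvent, with cell density n; Flory–Huggins mixing gives
the solvent chemical potential

    mu_s(θ_p) = log(1−θ_p) + (1 − 1/N) θ_p + χ θ_p²,

and cells act through the saturating traction potential
G(n) = τ₀n²/(1+λn²).  The imbalance `mu_s − mu_s^e + θ_p G(n)` across the
free surface drives solvent in (swelling) or out (contraction), moderated
by the interface resistance R and the polymer–solvent drag ξ.

The package provides three layers:

- **`gelfilm.uniform`** — spatially uniform films collapse to a single
  stiff ODE for the scaled half-height h(t), with θ_p = θ_I/h², n = n_I/h²
  and L = h exact; integrated adaptively to equilibrium.
- **`gelfilm.equilibria`** — bracketed root-finding for the uniform
  equilibria and the closed-form short-time response to cosine
  perturbations (the stability statistic z = θ*f''(θ*) − traction terms;
  z > 0 means perturbations of θ_p and h decay).
- **`gelfilm.solver`** — the full 1D moving-boundary thin-film system on a
  fixed domain, in conservative (Q = θ_p h, W = (1−θ_p)h) form, advanced
  by a Crank–Nicolson scheme with Picard-converged coefficients,
  cumulative-trapezoid velocity integration, and a mass audit.

`gelfilm.presets` holds the published scenario configurations
(`fig2a` … `fig9_zeroD`), exported as JSON configs under `examples/`, and
`gelfilm.cli` exposes them as a command line.

## Worked example

A uniform cell-free film (θ_I = 0.6, χ = 0.75, N = 100, R = 1) swells
because mu_s(0.6) < 0:

```python
>>> import gelfilm as g
>>> params, init = g.preset("fig2a")
>>> traj = g.integrate_uniform(0.6, 0.0, params)
>>> traj.summary()["equilibrium_2dp"]
{'theta_star': 0.45, 'n_star': 0.0, 'h_star': 1.16, 'L_star': 1.16}
```

The film dilutes to θ* = 0.45 while height and length both grow 16 %
(equal by construction: L = h for uniform films).  Adding cells with
traction τ₀ = 1 flips the outcome to contraction:

```python
>>> g.integrate_uniform(0.6, 1.0, params).summary()["equilibrium_2dp"]
{'theta_star': 0.86, 'n_star': 1.44, 'h_star': 0.83, 'L_star': 0.83}
```

With a spatially perturbed initial polymer fraction the full solver shows
the signature behaviour of the thin film — composition flattens but the
height keeps a permanent imprint of the initial non-uniformity:

```python
>>> import numpy as np
>>> params, init = g.preset("fig4")   # theta_I = 0.6 + 0.02 cos(pi X)
>>> state = g.make_initial_state(init, g.make_grid(41))
>>> res = g.advance(state, params, T_end=400.0, dT=1e-3)  # ~90 s
>>> round(float(np.mean(res.final.theta_p)), 2), round(g.amplitude(res.final.h), 3)
(0.45, 0.019)
```

The same runs are available from the shell:

```sh
gelfilm uniform  --config examples/fig2a.json --out run_fig2a
gelfilm simulate --config examples/fig5.json  --out run_fig5
gelfilm report   --out run_fig5
```

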