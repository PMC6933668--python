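# lignokin

Two-phase substrate kinetics for the enzymatic hydrolysis of
lignocellulose, in batch and continuous membrane reactors.

Enzymatic saccharification of pretreated biomass shows a pronounced rate
slowdown that simple Michaelis–Menten-style models miss. `lignokin` models
it phenomenologically: cellulose is split into a **facile** population and a
**recalcitrant** population of reduced enzyme accessibility, and the lumped
enzyme cocktail partitions at equilibrium among free solution, the two
glucan pools, xylan, and unproductive complexes with soluble lignin and
product sugars,

    𝒟 = 1 + κ_RF·λ_FR + κ_RX·λ_XR + (ε_l/c̃_GR)(K_dR + κ_RL·c_sL + κ_Rs·c_ss),
    c̃_EGR = c̃_ET/𝒟,   c̃_EGF = κ_RF·λ_FR·c̃_ET/𝒟,   c̃_EX = κ_RX·λ_XR·c̃_ET/𝒟.

Adsorbed enzyme hydrolyzes its substrate by first-order kinetics
(−r̃_i = k_i·c̃_Ei), lignin is co-solubilized in proportion to carbohydrate
digestion (r̃_L = k_L·c̃_L·(r̃_GR + r̃_X)), and the resulting ODE system runs
as a well-mixed batch or as a constant-mass CSTR with ultrafiltration
permeate, purge, and partial soluble-enzyme retention (η_E = 0.5). The
package is aimed at bioprocess engineers who need a reaction model cheap
enough for reactor design, parameter studies, and flowsheet or CFD
coupling.

It provides, as plain Python APIs with a thin CLI on top:

- `slurry` / `partition` / `kinetics` — the concentration algebra, the
  closed-form six-way enzyme partition, and the rate laws;
- `reactors` — batch and continuous membrane-reactor (CEH) simulation;
- `calibration` — constrained multi-start Nelder–Mead least squares for the
  nine model parameters;
- `sensitivity` — one-at-a-time ±30% parameter sweeps;
- `synthetic` — the batch campaign and continuous run designs as
  code-generated datasets with optional measurement noise;
- `io` / `cli` — YAML configs, CSV interchange,
  `lignokin simulate-batch|simulate-ceh|fit|sensitivity|gen-data`.

## Worked example

```python
import numpy as np
from lignokin import BatchCondition, ModelParams, simulate_batch

cond = BatchCondition(f_is0=0.10, lambda_E=0.020,   # 10% solids, 20 mg/g
                      rho_g=5.0, rho_x=15.0, rho_sL=1.0)
traj = simulate_batch(cond, ModelParams())
for t in (4, 24, 168):
    i = int(np.searchsorted(traj.t, t))
    print(f"t={t:3d} h  glucose {traj.c_g[i]:5.1f} g/L  "
          f"f_is {traj.f_is[i]:.4f}  X_t {traj.X_t[i]:.3f}")
```

prints

```
t=  4 h  glucose  26.7 g/L  f_is 0.0570  X_t 0.309
t= 24 h  glucose  52.0 g/L  f_is 0.0313  X_t 0.687
t=168 h  glucose  69.1 g/L  f_is 0.0147  X_t 0.930
```

A third of the carbohydrate converts in the first four hours while the
facile glucan pool lasts; the remaining week of reaction crawls through the
poorly accessible recalcitrant pool — the biphasic signature the model
exists to capture. Insoluble solids fall from 10% to 1.5% as sugars and
co-solubilized lignin leave the solid phase.

The `examples/` directory holds one short script per capability (batch,
continuous reactor, enzyme partition, sensitivity, recovery, data
generation); each prints its numbers with a line on what they mean.

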