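"""Small-scale parameter-recovery check (runs in ~1 min).

Noiseless observations are generated from the reference parameter set for
two batch conditions, then k_R and y_F0 are refit from a start perturbed
40% off truth.  The full-campaign, all-parameter version of this experiment
is what scripts/acceptance.py runs.
"""

from lignokin import ModelParams
from lignokin.calibration import FitOptions, ParamSpec, default_param_specs, fit
from lignokin.synthetic import NoiseModel, generate_batch_set

truth = ModelParams()
datasets = generate_batch_set(
    truth, noise=NoiseModel(rel_sd_sugars=0.0, rel_sd_fis=0.0, seed=0)
)[:3]

specs = [
    s if s.name in ("k_R", "y_F0")
    else ParamSpec(s.name, s.lower, s.upper, s.transform, free=False)
    for s in default_param_specs()
]
start = truth.with_values(k_R=14713.0 * 1.4, y_F0=0.42)
result = fit(
    datasets,
    init=start,
    specs=specs,
    options=FitOptions(n_starts=2, maxfev_start=300, maxfev_polish=400, seed=0),
)

print(f"objective at optimum: {result.objective:.3e}")
for name, true_val in [("k_R", 14713.0), ("y_F0", 0.60)]:
    got = result.params.get(name)
    print(f"{name:5s} truth {true_val:10.4g}  recovered {got:10.4g}"
          f"  ({abs(got - true_val) / true_val:.2%} off)")
print(
    "\nWith noiseless self-generated data the objective collapses to ~0 and"
    "\nboth parameters return to their generating values."
)
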