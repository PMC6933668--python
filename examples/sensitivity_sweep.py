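"""One-at-a-time ±30% parameter sweeps around the best-fit point.

Prints the 168-h batch conversion at each delta for the four headline
parameters, showing which knobs move the outcome and which do not.
"""

from lignokin import BatchCondition, ModelParams
from lignokin.sensitivity import SweepSpec, run_sweep

cond = BatchCondition(f_is0=0.10, lambda_E=0.020, rho_g=5, rho_x=15, rho_sL=1)
params = ModelParams()

print("parameter    X_t(168h) at -30%   base   +30%")
for name in ("k_R", "kappa_Rs", "kappa_RF", "y_F0", "K_dR"):
    res = run_sweep(SweepSpec(parameter=name, batch=cond), params)
    ends = {d: res.trajectories[d].X_t[-1] for d in (-0.30, 0.0, 0.30)}
    print(
        f"{name:10s} {ends[-0.30]:14.3f} {ends[0.0]:8.3f} {ends[0.30]:8.3f}"
    )

print(
    "\nk_R (rate) and kappa_Rs (sugar inhibition) pull with similar force in"
    "\nopposite directions; y_F0 moves the extent reached before slowdown;"
    "\nK_dR barely matters because nearly all enzyme is already adsorbed."
)
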