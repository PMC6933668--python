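"""Least-squares objective and constrained simplex fitting."""

import numpy as np
import pandas as pd
import pytest

from lignokin import BatchCondition, ModelParams, simulate_batch
from lignokin.calibration import (
    Dataset,
    FitOptions,
    ParamSpec,
    default_param_specs,
    fit,
    objective,
)
from lignokin.slurry import DomainError


def quick_dataset(params, cond=None, times=(8.0, 24.0, 72.0)):
    """Noiseless observations simulated at a few times."""
    cond = cond or BatchCondition(rho_g=5, rho_x=15, rho_sL=1)
    t = np.asarray(times)
    traj = simulate_batch(cond, params, t_eval=np.concatenate([[0.0], t]))
    fis_t = np.array([times[1], times[-1]])
    obs = pd.DataFrame(
        {
            "time_h": np.concatenate([t, t, fis_t]),
            "observable": ["glucose_g_per_L"] * len(t)
            + ["xylose_g_per_L"] * len(t)
            + ["f_is"] * len(fis_t),
            "value": np.concatenate(
                [
                    np.interp(t, traj.t, traj.c_g),
                    np.interp(t, traj.t, traj.c_x),
                    np.interp(fis_t, traj.t, traj.f_is),
                ]
            ),
        }
    )
    return Dataset(condition=cond, observations=obs, label="quick")


class TestObjective:
    def test_zero_for_self_generated_data(self, reference_params, noiseless_batch_set):
        assert objective(reference_params, noiseless_batch_set) < 1e-10

    def test_perturbed_parameters_score_worse(
        self, reference_params, noiseless_batch_set
    ):
        worse = reference_params.with_values(k_R=20000.0, y_F0=0.4)
        assert objective(worse, noiseless_batch_set) > objective(
            reference_params, noiseless_batch_set
        )

    def test_hand_summed_toy_objective(self, reference_params):
        """Objective equals an independently computed Σ w·((model−obs)/scale)²
        on a three-point glucose-only toy dataset."""
        cond = BatchCondition(rho_g=5, rho_x=15, rho_sL=1)
        t = np.array([8.0, 24.0, 72.0])
        traj = simulate_batch(
            cond, reference_params, t_eval=np.concatenate([[0.0], t])
        )
        model_g = np.interp(t, traj.t, traj.c_g)
        values = np.array([20.0, 40.0, 55.0])
        weights = np.array([1.0, 2.0, 0.5])
        ds = Dataset(
            condition=cond,
            observations=pd.DataFrame(
                {
                    "time_h": t,
                    "observable": ["glucose_g_per_L"] * 3,
                    "value": values,
                    "weight": weights,
                }
            ),
        )
        expected = float(
            np.sum(weights * ((model_g - values) / values.max()) ** 2)
        )
        assert objective(reference_params, ds_list := [ds]) == pytest.approx(
            expected, rel=1e-6
        )
        # ordering of datasets does not change the sum
        assert objective(reference_params, ds_list * 2) == pytest.approx(
            2 * expected, rel=1e-6
        )

    def test_empty_dataset_list_rejected(self, reference_params):
        with pytest.raises(DomainError):
            objective(reference_params, [])


class TestParamSpecTransforms:
    @pytest.mark.parametrize("spec", default_param_specs())
    def test_roundtrip_inside_bounds(self, spec):
        lo, hi = spec.lower, spec.upper
        interior = lo + 0.37 * (hi - lo) if spec.transform == "logit" else (
            np.sqrt(max(lo, 1e-12) * hi)
        )
        u = spec.to_unconstrained(interior)
        assert spec.from_unconstrained(u) == pytest.approx(interior, rel=1e-9)

    def test_unconstrained_always_maps_into_box(self):
        spec = ParamSpec("k_R", 1.0, 1e6, "log-logit")
        for u in (-50.0, -1.0, 0.0, 1.0, 50.0):
            x = spec.from_unconstrained(u)
            assert spec.lower <= x <= spec.upper

    def test_bound_detection(self):
        spec = ParamSpec("kappa_Rs", 0.1, 50.0, "log-logit")
        assert spec.on_bound(50.0)
        assert spec.on_bound(50.0 * (1 - 1e-8))
        assert not spec.on_bound(45.0)


class TestFit:
    def test_start_at_truth_stays_at_truth(self, reference_params):
        ds = quick_dataset(reference_params)
        specs = [
            s if s.name in ("k_R", "y_F0") else ParamSpec(
                s.name, s.lower, s.upper, s.transform, free=False
            )
            for s in default_param_specs()
        ]
        res = fit(
            [ds],
            init=reference_params,
            specs=specs,
            options=FitOptions(n_starts=1, maxfev_start=50, maxfev_polish=50),
        )
        assert res.objective < 1e-10
        assert res.params.get("k_R") == pytest.approx(14713.0, rel=1e-3)

    def test_recovers_two_parameters_from_perturbed_start(self, reference_params):
        """Noiseless data, k_R and y_F0 free, start 40% off: both recovered."""
        ds = quick_dataset(reference_params)
        specs = [
            s if s.name in ("k_R", "y_F0") else ParamSpec(
                s.name, s.lower, s.upper, s.transform, free=False
            )
            for s in default_param_specs()
        ]
        start = reference_params.with_values(k_R=14713.0 * 1.4, y_F0=0.42)
        res = fit(
            [ds],
            init=start,
            specs=specs,
            options=FitOptions(n_starts=1, maxfev_start=400, maxfev_polish=400),
        )
        assert res.params.get("k_R") == pytest.approx(14713.0, rel=0.05)
        assert res.params.get("y_F0") == pytest.approx(0.60, rel=0.05)

    def test_bound_activity_flag_for_parameter_at_bound(self, reference_params):
        """Data generated at kappa_Rs = 50 with the box ending there: the
        fitted parameter is reported as bound-active."""
        ds = quick_dataset(reference_params)  # truth kappa_Rs = 50
        specs = [
            s if s.name == "kappa_Rs" else ParamSpec(
                s.name, s.lower, s.upper, s.transform, free=False
            )
            for s in default_param_specs()
        ]
        start = reference_params.with_values(kappa_Rs=25.0)
        res = fit(
            [ds],
            init=start,
            specs=specs,
            options=FitOptions(n_starts=1, maxfev_start=200, maxfev_polish=200),
        )
        assert res.bound_active["kappa_Rs"]
        assert res.params.get("kappa_Rs") == pytest.approx(50.0, rel=1e-6)

    def test_order_invariance(self, reference_params):
        a = quick_dataset(reference_params)
        b = quick_dataset(
            reference_params, cond=BatchCondition(f_is0=0.05, rho_g=5, rho_x=15)
        )
        specs = [
            s if s.name == "k_R" else ParamSpec(
                s.name, s.lower, s.upper, s.transform, free=False
            )
            for s in default_param_specs()
        ]
        opts = FitOptions(n_starts=1, maxfev_start=100, maxfev_polish=100)
        r1 = fit([a, b], init=reference_params, specs=specs, options=opts)
        r2 = fit([b, a], init=reference_params, specs=specs, options=opts)
        assert r1.params.get("k_R") == pytest.approx(r2.params.get("k_R"), rel=1e-12)

    def test_no_datasets_rejected(self, reference_params):
        with pytest.raises(DomainError):
            fit([], init=reference_params)


class TestDatasetValidation:
    def test_unknown_observable_rejected(self):
        with pytest.raises(DomainError):
            Dataset(
                condition=BatchCondition(),
                observations=pd.DataFrame(
                    {"time_h": [1.0], "observable": ["ethanol"], "value": [1.0]}
                ),
            )

    def test_time_beyond_horizon_rejected(self):
        with pytest.raises(DomainError):
            Dataset(
                condition=BatchCondition(duration_h=24.0),
                observations=pd.DataFrame(
                    {
                        "time_h": [48.0],
                        "observable": ["glucose_g_per_L"],
                        "value": [1.0],
                    }
                ),
            )
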