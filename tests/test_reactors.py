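"""Batch and continuous reactor assembly, integration, and stream algebra."""

import numpy as np
import pytest

from conftest import random_state_arrays
from lignokin import (
    BatchCondition,
    ModelParams,
    StreamSpec,
    batch_rhs,
    cstr_rhs,
    initial_state,
    purge_from_closure,
    residence_time,
    simulate_batch,
    simulate_ceh,
)
from lignokin.kinetics import RateParams
from lignokin.reactors import ConfigError, STATE_NAMES
from lignokin.slurry import DomainError


class TestInitialState:
    def test_reference_condition_glucan_split(self):
        cond = BatchCondition(f_is0=0.10)
        s = initial_state(cond, ModelParams())  # y_F0 = 0.60
        assert s.f_GF == pytest.approx(0.0372, rel=1e-12)
        assert s.f_GR == pytest.approx(0.0248, rel=1e-12)
        assert s.f_X == pytest.approx(0.006, rel=1e-12)
        assert s.f_L == pytest.approx(0.022, rel=1e-12)
        assert s.f_O == pytest.approx(0.010, rel=1e-12)

    def test_enzyme_loading(self):
        s = initial_state(BatchCondition(f_is0=0.10, lambda_E=0.020))
        assert s.f_ET == pytest.approx(1.24e-3, rel=1e-12)

    def test_all_facile_when_yF0_is_one(self):
        s = initial_state(BatchCondition(), ModelParams(y_F0=1.0))
        assert s.f_GR == 0.0

    def test_background_solubles_use_liquid_basis(self):
        # 15 g/L xylose in 90% liquid at 1000 kg/m3 -> mass fraction 0.0135
        s = initial_state(BatchCondition(f_is0=0.10, rho_x=15.0))
        assert s.f_x == pytest.approx(15.0 * 0.9 / 1000.0, rel=1e-12)

    def test_inconsistent_solids_composition_rejected(self):
        with pytest.raises(DomainError):
            BatchCondition(w_G=0.62, w_X=0.06, w_L=0.22, w_O=0.20)


class TestBatchRHS:
    def test_zero_enzyme_is_inert(self):
        y = np.array([0.02, 0.04, 0.006, 0.022, 0.01, 0.01, 0.01, 0.001, 0.0])
        assert np.all(batch_rhs(y, ModelParams()) == 0.0)

    def test_inerts_and_enzyme_are_conserved(self):
        y = np.array([0.02, 0.04, 0.006, 0.022, 0.01, 0.01, 0.01, 0.001, 1e-3])
        dy = batch_rhs(y, ModelParams())
        assert dy[4] == 0.0 and dy[8] == 0.0

    def test_hand_composed_against_partition_and_rates(self):
        """The RHS equals partition -> molar rates -> mass rates composed
        step-by-step through the public APIs."""
        from lignokin.kinetics import mass_rates, molar_rates
        from lignokin.partition import partition_enzyme
        from lignokin.slurry import SlurryState, slurry_density

        p = ModelParams()
        state = SlurryState(
            f_GR=0.02, f_GF=0.03, f_X=0.005, f_L=0.02, f_O=0.01,
            f_g=0.01, f_x=0.012, f_sL=0.001, f_ET=1e-3,
        )
        part = partition_enzyme(state, p.adsorption, p.catalog, p.density)
        rho_T = slurry_density(state, p.density)
        c_L = state.f_L * rho_T / p.catalog.mw_lignin
        rv = mass_rates(molar_rates(part, c_L, p.rates), p.catalog, rho_T)
        y = np.array([getattr(state, n) for n in STATE_NAMES])
        dy = batch_rhs(y, p)
        assert dy[0] == pytest.approx(rv.R_GR, rel=1e-12)
        assert dy[1] == pytest.approx(rv.R_GF, rel=1e-12)
        assert dy[2] == pytest.approx(rv.R_X, rel=1e-12)
        assert dy[3] == pytest.approx(rv.R_L, rel=1e-12)
        assert dy[5] == pytest.approx(rv.R_g, rel=1e-12)
        assert dy[6] == pytest.approx(rv.R_x, rel=1e-12)
        assert dy[7] == pytest.approx(rv.R_sL, rel=1e-12)

    def test_glucan_glucose_molar_balance_in_rhs(self):
        y = np.array([0.02, 0.04, 0.006, 0.022, 0.01, 0.01, 0.01, 0.001, 1e-3])
        dy = batch_rhs(y, ModelParams())
        molar = (dy[0] + dy[1]) / 162.14 + dy[5] / 180.16
        assert molar == pytest.approx(0.0, abs=1e-18)


class TestSimulateBatch:
    def test_no_kinetics_means_constant_states(self):
        params = ModelParams(rates=RateParams(k_R=0, k_F=0, k_X=0, k_L=0))
        traj = simulate_batch(BatchCondition(rho_g=5, rho_x=15), params)
        assert np.allclose(traj.y, traj.y[0], atol=1e-12)

    def test_zero_order_limit_glucose_rises_linearly(self):
        """All-facile substrate far above the free-enzyme scale: glucose
        production is zero order with slope MW_g·k_F·c̃_ET/ρ_T."""
        params = ModelParams(
            rates=RateParams(k_R=14713.0),
            y_F0=1.0,
        ).with_values(kappa_Rs=0.0, kappa_RL=0.0)
        cond = BatchCondition(
            f_is0=0.10, w_G=1.0, w_X=0.0, w_L=0.0, w_O=0.0, lambda_E=0.020,
            duration_h=1.0,
        )
        traj = simulate_batch(cond, params, t_eval=np.linspace(0, 0.5, 11))
        c_ET = 0.020 * 0.10 * 1000.0 / 65000.0
        slope = 180.16 * 14713.0 * c_ET / 1000.0
        measured = np.diff(traj.y[:, 5]) / np.diff(traj.t)
        assert measured[0] == pytest.approx(slope, rel=0.02)
        # linearity: slope at 0.5 h within 2% of the initial slope
        assert measured[-1] == pytest.approx(measured[0], rel=0.02)

    def test_glucose_bounded_by_stoichiometric_maximum(self, reference_params):
        cond = BatchCondition(rho_g=5, rho_x=15, rho_sL=1)
        traj = simulate_batch(cond, reference_params)
        f_G0 = traj.y[0, 0] + traj.y[0, 1]
        max_fg = (180.16 / 162.14) * f_G0 + traj.y[0, 5]
        assert traj.y[:, 5].max() <= max_fg * (1 + 1e-9)

    def test_biphasic_depletion_ordering(self, reference_params):
        """Facile glucan exhausts much earlier than recalcitrant glucan."""
        traj = simulate_batch(
            BatchCondition(rho_g=5, rho_x=15, rho_sL=1), reference_params
        )
        frac_F = traj.y[:, 1] / traj.y[0, 1]
        frac_R = traj.y[:, 0] / traj.y[0, 0]
        t_F90 = traj.t[np.argmax(frac_F < 0.10)]
        frac_R_then = np.interp(t_F90, traj.t, frac_R)
        assert frac_R_then > 0.50

    def test_glucan_glucose_inventory_conserved_over_168h(self, reference_params):
        traj = simulate_batch(
            BatchCondition(rho_g=5, rho_x=15, rho_sL=1), reference_params
        )
        inv = (traj.y[:, 0] + traj.y[:, 1]) / 162.14 + traj.y[:, 5] / 180.16
        assert np.max(np.abs(inv - inv[0])) / inv[0] < 1e-7


class TestConversion:
    def test_zero_at_start_and_monotone(self, reference_params):
        traj = simulate_batch(
            BatchCondition(rho_g=5, rho_x=15, rho_sL=1), reference_params
        )
        X = traj.X_t
        assert X[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(X) >= -1e-12)
        assert np.all((X >= -1e-12) & (X <= 1.0 + 1e-9))

    def test_complete_conversion_gives_unity(self, reference_params):
        """Substituting the stoichiometric sugar maxima yields X_t = 1."""
        cond = BatchCondition(f_is0=0.10)
        traj = simulate_batch(cond, reference_params, t_eval=[0.0, 1.0])
        cat = reference_params.catalog
        y_end = traj.y[-1].copy()
        f_G0 = traj.y[0, 0] + traj.y[0, 1]
        f_X0 = traj.y[0, 2]
        y_end[5] = traj.y[0, 5] + f_G0 / cat.r_g
        y_end[6] = traj.y[0, 6] + f_X0 / cat.r_x
        traj.y[-1] = y_end
        assert traj.X_t[-1] == pytest.approx(1.0, rel=1e-10)

    def test_no_carbohydrate_denominator_rejected(self, reference_params):
        cond = BatchCondition(w_G=0.0, w_X=0.0, w_L=0.5, w_O=0.5)
        traj = simulate_batch(cond, reference_params, t_eval=[0.0, 1.0])
        with pytest.raises(DomainError):
            _ = traj.X_t


class TestStreams:
    @pytest.mark.parametrize(
        "m_s, m_e, m_m, purge",
        [(0.42, 0.138, 0.276, 0.282), (0.426, 0.072, 0.222, 0.276),
         (0.348, 0.054, 0.152, 0.250)],
    )
    def test_purge_from_closure(self, m_s, m_e, m_m, purge):
        assert purge_from_closure(m_s, m_e, m_m) == pytest.approx(purge, abs=1e-12)

    def test_infeasible_permeate_rejected(self):
        with pytest.raises(ConfigError):
            purge_from_closure(0.1, 0.0, 0.2)

    @pytest.mark.parametrize(
        "m_s, m_e, m_m, tau", [(0.42, 0.138, 0.276, 17.7), (0.426, 0.072, 0.222, 18.1),
                               (0.348, 0.054, 0.152, 20.0)],
    )
    def test_residence_time_matches_nominal(self, m_s, m_e, m_m, tau):
        spec = StreamSpec(m_s_in=m_s, m_e_in=m_e, m_m_out=m_m, m_T=5.0)
        assert residence_time(spec) == pytest.approx(tau, abs=0.05)

    def test_residence_halves_when_purge_doubles(self):
        a = StreamSpec(m_s_in=0.4, m_e_in=0.1, m_m_out=0.25)
        b = StreamSpec(m_s_in=0.8, m_e_in=0.2, m_m_out=0.50)
        assert residence_time(b) == pytest.approx(residence_time(a) / 2, rel=1e-12)

    def test_zero_purge_is_infinite_residence(self):
        spec = StreamSpec(m_s_in=0.1, m_e_in=0.1, m_m_out=0.2)
        assert residence_time(spec) == np.inf

    def test_closure_violation_rejected(self):
        with pytest.raises(ConfigError):
            StreamSpec(m_s_in=0.4, m_e_in=0.1, m_m_out=0.2, m_p_out=0.5)


class TestCSTR:
    def test_zero_flow_reduces_to_batch(self, reference_params):
        """With all streams off, the CSTR RHS equals the batch RHS exactly."""
        spec = StreamSpec(m_s_in=0.0, m_e_in=0.0, m_m_out=0.0)
        rng = np.random.default_rng(11)
        for y in random_state_arrays(rng, 100):
            np.testing.assert_array_equal(
                cstr_rhs(y, spec, reference_params), batch_rhs(y, reference_params)
            )

    def test_washout_steady_state_with_zero_kinetics(self):
        """No reaction: insolubles settle at (ṁ_s/ṁ_p)·f_feed exactly."""
        params = ModelParams(rates=RateParams(k_R=0, k_F=0, k_X=0, k_L=0))
        feed = BatchCondition(f_is0=0.05)
        spec = StreamSpec(
            m_s_in=0.42, m_e_in=0.138, m_m_out=0.276, feed=feed, startup_h=1.0
        )
        startup = BatchCondition(f_is0=0.05, lambda_E=0.0)
        traj = simulate_ceh(spec, startup, params, duration_h=400.0, dt_out=5.0)
        feed_state = initial_state(feed, params.with_values())
        expect = (0.42 / 0.282) * (feed_state.f_GR + feed_state.f_GF
                                   + feed_state.f_X + feed_state.f_L + feed_state.f_O)
        assert traj.f_is[-1] == pytest.approx(expect, rel=1e-5)

    def test_reaches_steady_state(self, reference_params):
        from lignokin.synthetic import ceh_design

        run = ceh_design()[0]
        traj = simulate_ceh(
            run.streams, run.startup, reference_params, duration_h=300.0, dt_out=2.0
        )
        y_end = traj.y[-1]
        dy = cstr_rhs(y_end, run.streams, reference_params)
        assert np.linalg.norm(dy) < 1e-6

    def test_switch_time_flagged(self, reference_params):
        from lignokin.synthetic import ceh_design

        run = ceh_design()[0]
        traj = simulate_ceh(run.streams, run.startup, reference_params, duration_h=10.0)
        assert traj.switch_time == run.streams.startup_h
        assert traj.t[0] == 0.0 and traj.t[-1] == pytest.approx(
            run.streams.startup_h + 10.0
        )

    def test_less_permeate_more_washout_dilution(self, reference_params):
        """At fixed feeds, shrinking the permeate grows the purge and lowers
        the steady insoluble-solids fraction."""
        feed = BatchCondition(f_is0=0.075)
        startup = BatchCondition(f_is0=0.075, lambda_E=0.010)
        out = []
        for m_m in (0.25, 0.10):
            spec = StreamSpec(m_s_in=0.42, m_e_in=0.14, m_m_out=m_m, feed=feed)
            traj = simulate_ceh(
                spec, startup, reference_params, duration_h=250.0, dt_out=5.0
            )
            out.append(traj.f_is[-1])
        assert out[1] < out[0]
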