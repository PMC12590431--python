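"""Compaction-thermal-viability simulator: physics and calibration."""

import dataclasses
import math

import numpy as np
import pytest

from probitab.design import ProcessPoint
from probitab.oracle import (Anchor, CompactionOracle, CompactionSchedule,
                             DPCParams, MaterialParams, OracleParams,
                             ThermalField, ToleranceParams, calibrate,
                             default_anchors, default_params, dpc_surfaces,
                             integrated_kill_survival, load_params,
                             save_params, survival_of_history,
                             volume_average_survival)


class TestYieldSurfaces:
    def test_shear_surface_at_cohesion_intercept(self):
        # at p = 0 the shear line crosses q = d
        fs, _, _ = dpc_surfaces(0.0, 2.0, DPCParams(d=2.0))
        assert fs == pytest.approx(0.0, abs=1e-12)

    def test_shear_surface_linear_form(self):
        # Fs = q - p tan(beta) - d; with d=1, beta=45deg, p=2, q=4 -> Fs = 1
        fs, _, _ = dpc_surfaces(2.0, 4.0, DPCParams(d=1.0, beta=45.0))
        assert fs == pytest.approx(1.0, abs=1e-12)

    def test_cap_apex_on_cap_surface(self):
        # at zero plastic strain pa = 0, so the cap apex sits at
        # (p, q) = (R*(d + pa tanb), 0) = (R*d, 0)
        params = DPCParams(d=2.0, R_ecc=0.6)
        _, fc, _ = dpc_surfaces(0.6 * 2.0, 0.0, params)
        assert fc == pytest.approx(0.0, abs=1e-12)

    def test_non_finite_stress_rejected(self):
        with pytest.raises(ValueError):
            dpc_surfaces(np.nan, 1.0, DPCParams())

    @pytest.mark.parametrize("kw", [
        {"d": -1.0}, {"beta": 0.0}, {"beta": 90.0}, {"alpha_t": 0.5},
        {"R_ecc": 0.0},
    ])
    def test_parameter_invariants(self, kw):
        with pytest.raises(ValueError):
            DPCParams(**kw)


class TestParamBundles:
    @pytest.mark.parametrize("kw", [
        {"rho": -1.0}, {"eta_pl": 0.0}, {"eta_pl": 1.5}, {"K_rad": 1.0},
        {"mu_fric": -0.1},
    ])
    def test_material_invariants(self, kw):
        with pytest.raises(ValueError):
            MaterialParams(**kw)

    def test_tolerance_invariants(self):
        with pytest.raises(ValueError):
            ToleranceParams(z_T=0.0)
        with pytest.raises(ValueError):
            ToleranceParams(s_max=0.5)

    def test_kinetics_flag_validated(self):
        with pytest.raises(ValueError):
            OracleParams(kinetics="instant")
        with pytest.raises(ValueError):
            OracleParams(D_crit_s=0.0)

    def test_dict_round_trip(self):
        p = default_params(calibrated=True)
        assert OracleParams.from_dict(p.to_dict()) == p

    def test_json_round_trip(self, tmp_path):
        p = default_params(calibrated=True)
        save_params(p, tmp_path / "p.json")
        assert load_params(tmp_path / "p.json") == p


class TestSchedule:
    def test_no_pre_segments_without_precompression(self):
        sched = CompactionOracle().build_schedule(ProcessPoint(100.0, 0.0, 200.0))
        assert not any(str(lbl).startswith("pre") for lbl in sched.labels)
        assert not any(lbl == "gap" for lbl in sched.labels)

    def test_pre_segments_present_with_precompression(self):
        sched = CompactionOracle().build_schedule(ProcessPoint(100.0, 50.0, 200.0))
        labels = set(sched.labels)
        assert {"pre-ramp", "pre-unload", "gap", "main-ramp",
                "main-unload"} <= labels

    def test_doubling_speed_halves_stroke_durations(self):
        oracle = CompactionOracle()
        slow = oracle.build_schedule(ProcessPoint(100.0, 0.0, 200.0))
        fast = oracle.build_schedule(ProcessPoint(200.0, 0.0, 200.0))
        assert fast.duration == pytest.approx(slow.duration / 2.0, rel=1e-12)

    def test_peak_pressure_exact(self):
        sched = CompactionOracle().build_schedule(ProcessPoint(180.0, 0.0, 208.0))
        assert sched.P.max() == pytest.approx(208.0, abs=1e-12)

    def test_pressure_monotone_on_main_ramp(self):
        sched = CompactionOracle().build_schedule(ProcessPoint(100.0, 0.0, 300.0))
        on_ramp = sched.P[sched.labels == "main-ramp"]
        assert (np.diff(on_ramp) > 0).all()

    def test_degenerate_equal_pressures_dwell(self):
        sched = CompactionOracle().build_schedule(ProcessPoint(100.0, 200.0, 200.0))
        assert (sched.labels == "main-ramp").sum() == 1

    def test_speed_floor_applied_at_zero_speed(self):
        sched = CompactionOracle().build_schedule(ProcessPoint(0.0, 0.0, 200.0))
        assert np.isfinite(sched.duration) and sched.duration > 0


class TestHeatSources:
    def test_zero_pressure_gives_zero_sources(self):
        oracle = CompactionOracle()
        sched = oracle.build_schedule(ProcessPoint(100.0, 20.0, 200.0))
        qp, qf = oracle.heat_sources(sched)
        gap = sched.labels == "gap"
        assert (qp[gap] == 0).all() and (qf[gap] == 0).all()

    def test_unloads_are_elastic(self):
        oracle = CompactionOracle()
        sched = oracle.build_schedule(ProcessPoint(100.0, 0.0, 200.0))
        unload = sched.labels == "main-unload"
        qp, qf = oracle.heat_sources(sched)
        assert (qp[unload] == 0).all()
        assert (qf[unload] > 0).all()  # sliding against a loaded wall

    def test_plastic_source_magnitude(self):
        # q_p = eta_pl * P * |deps_v/dt| = 0.9 * 100e6 Pa * 0.5 /s
        params = dataclasses.replace(
            default_params(False),
            material=dataclasses.replace(MaterialParams(), eta_pl=0.9))
        oracle = CompactionOracle(params)
        sched = CompactionSchedule(
            t=np.array([1.0]), P=np.array([100.0]), dev_dt=np.array([0.5]),
            v_slip=np.array([0.0]), dt=np.array([1.0]),
            labels=np.array(["main-ramp"], dtype=object),
            peak_pre=0.0, peak_main=100.0)
        qp, _ = oracle.heat_sources(sched)
        assert qp[0] == pytest.approx(4.5e7)

    def test_friction_flux_formula(self):
        # q_f = mu * K_rad * P * v_slip
        m = MaterialParams(mu_fric=0.2, K_rad=0.4)
        oracle = CompactionOracle(dataclasses.replace(default_params(False),
                                                      material=m))
        sched = CompactionSchedule(
            t=np.array([1.0]), P=np.array([50.0]), dev_dt=np.array([0.0]),
            v_slip=np.array([0.01]), dt=np.array([1.0]),
            labels=np.array(["main-ramp"], dtype=object),
            peak_pre=0.0, peak_main=50.0)
        _, qf = oracle.heat_sources(sched)
        assert qf[0] == pytest.approx(0.2 * 0.4 * 50e6 * 0.01)


def _dwell_schedule(n, dt, P=0.0, dev=0.0, v=0.0):
    return CompactionSchedule(
        t=np.cumsum(np.full(n, dt)), P=np.full(n, P), dev_dt=np.full(n, dev),
        v_slip=np.full(n, v), dt=np.full(n, dt),
        labels=np.full(n, "main-ramp", dtype=object),
        peak_pre=0.0, peak_main=max(P, 1.0))


class TestThermalSolver:
    def test_zero_sources_stay_at_tool_temperature(self):
        oracle = CompactionOracle()
        fld = oracle.solve_thermal(_dwell_schedule(50, 0.01))
        assert np.allclose(fld.T_final, oracle.params.material.T_tool,
                           atol=1e-12)
        assert np.allclose(fld.peak_T, oracle.params.material.T_tool,
                           atol=1e-12)

    def test_lumped_adiabatic_heating(self):
        # insulated compact with uniform source: dT = qp * t / (rho * Cp)
        # qp = 1.0 * 2 MPa * 1.0 /s = 2e6 W/m^3; over 1 s with rho*Cp = 2e6
        # that is exactly +1 K on every shell
        m = MaterialParams(rho=1000.0, Cp=2000.0, eta_pl=1.0, mu_fric=0.0,
                           h_wall=0.0, h_punch=0.0)
        oracle = CompactionOracle(dataclasses.replace(default_params(False),
                                                      material=m))
        fld = oracle.solve_thermal(_dwell_schedule(100, 0.01, P=2.0, dev=1.0))
        assert np.allclose(fld.T_final, m.T_tool + 1.0, atol=1e-9)

    def test_energy_conservation_when_insulated(self, space):
        m = MaterialParams(h_wall=0.0, h_punch=0.0)
        oracle = CompactionOracle(dataclasses.replace(default_params(False),
                                                      material=m))
        sched = oracle.build_schedule(ProcessPoint(3000.0, 40.0, 300.0))
        fld = oracle.solve_thermal(sched)
        rcp = m.rho * m.Cp
        sensible = float(np.sum(rcp * fld.shell_volumes
                                * (fld.T_final - m.T_tool)))
        deposited = fld.total_plastic_J + fld.total_friction_J
        assert sensible == pytest.approx(deposited, rel=5e-3)

    def test_temperature_never_below_tooling(self, oracle):
        for p in (ProcessPoint(5000.0, 0.0, 400.0),
                  ProcessPoint(100.0, 50.0, 150.0)):
            fld = oracle.solve_thermal(oracle.build_schedule(p))
            assert (fld.peak_T >= oracle.params.material.T_tool - 1e-9).all()

    def test_grid_and_time_refinement(self, oracle):
        """Halving neither the mesh nor the step budget moves the answer."""
        fine = dataclasses.replace(oracle.params, n_shells=400, n_ramp=1200,
                                   n_unload=320, n_gap=320)
        fine_oracle = CompactionOracle(fine)
        for p in (ProcessPoint(4500.0, 25.0, 400.0),
                  ProcessPoint(180.0, 133.0, 374.0)):
            coarse_fld = oracle.solve_thermal(oracle.build_schedule(p))
            fine_fld = fine_oracle.solve_thermal(
                fine_oracle.build_schedule(p), substeps=4)
            s_coarse = volume_average_survival(coarse_fld,
                                               oracle.params.tolerance)
            s_fine = volume_average_survival(fine_fld,
                                             oracle.params.tolerance)
            assert s_coarse == pytest.approx(s_fine, rel=0.01)
            dT_c = coarse_fld.peak_T.max() - oracle.params.material.T_tool
            dT_f = fine_fld.peak_T.max() - oracle.params.material.T_tool
            assert dT_c == pytest.approx(dT_f, rel=0.01)

    def test_too_few_shells_rejected(self, oracle):
        with pytest.raises(ValueError):
            oracle.solve_thermal(_dwell_schedule(5, 0.01), n_shells=2)

    def test_non_finite_temperatures_raise(self):
        oracle = CompactionOracle()
        sched = _dwell_schedule(5, 0.01, P=np.nan, dev=1.0)
        with pytest.raises(FloatingPointError):
            oracle.solve_thermal(sched)


class TestSurvivalLaws:
    def test_below_onset_full_survival(self):
        tol = ToleranceParams(T_crit=41.0, z_T=9.0, s_max=1.0)
        assert survival_of_history(30.0, tol) == 1.0

    def test_one_z_above_onset_one_log_cycle(self):
        tol = ToleranceParams(T_crit=41.0, z_T=9.0, s_max=1.0)
        assert survival_of_history(50.0, tol) == pytest.approx(0.1)

    def test_plateau_scaling(self):
        tol = ToleranceParams(T_crit=41.0, z_T=9.0, s_max=1.05)
        assert survival_of_history(41.0, tol) == pytest.approx(1.05)

    def test_non_finite_peak_rejected(self):
        with pytest.raises(ValueError):
            survival_of_history(np.inf, ToleranceParams())

    def test_volume_average_constant_temperature(self):
        fld = ThermalField(r=np.ones(4), shell_volumes=np.ones(4),
                           peak_T=np.full(4, 50.0), T_final=np.full(4, 25.0),
                           total_plastic_J=0.0, total_friction_J=0.0)
        tol = ToleranceParams(T_crit=41.0, z_T=9.0)
        assert volume_average_survival(fld, tol) == pytest.approx(
            survival_of_history(50.0, tol))

    def test_volume_average_two_equal_shells(self):
        # survivals 1.0 and 0.5 with equal volume -> 0.75
        tol = ToleranceParams(T_crit=41.0, z_T=9.0)
        T_half = 41.0 + 9.0 * np.log10(2.0)
        fld = ThermalField(r=np.array([0.5, 1.5]),
                           shell_volumes=np.array([1.0, 1.0]),
                           peak_T=np.array([30.0, T_half]),
                           T_final=np.zeros(2),
                           total_plastic_J=0.0, total_friction_J=0.0)
        assert volume_average_survival(fld, tol) == pytest.approx(0.75)

    def test_volume_average_matches_brute_force(self):
        rng = np.random.default_rng(0)
        vols = rng.random(20) + 0.1
        peaks = 30.0 + 40.0 * rng.random(20)
        fld = ThermalField(r=np.arange(20.0), shell_volumes=vols,
                           peak_T=peaks, T_final=peaks,
                           total_plastic_J=0.0, total_friction_J=0.0)
        tol = ToleranceParams(T_crit=41.0, z_T=9.0)
        ref = sum(v * survival_of_history(t, tol)
                  for v, t in zip(vols, peaks)) / vols.sum()
        assert volume_average_survival(fld, tol) == pytest.approx(ref, abs=1e-6)

    def test_integrated_kinetics_survival_bounds_and_scaling(self):
        tol = ToleranceParams(T_crit=41.0, z_T=9.0)
        history = np.array([[30.0, 60.0], [35.0, 55.0], [30.0, 50.0]])
        dt = np.full(3, 0.1)
        vols = np.array([1.0, 1.0])
        s1 = integrated_kill_survival(history, dt, vols, tol, D_crit_s=1.0)
        s10 = integrated_kill_survival(history, dt, vols, tol, D_crit_s=10.0)
        assert 0.0 < s1 < 1.0
        assert s10 > s1  # slower kill kinetics -> higher survival
        cold = integrated_kill_survival(history - 40.0, dt, vols, tol, 1.0)
        assert cold == pytest.approx(1.0)


class TestEndToEnd:
    def test_deterministic(self, oracle):
        p = ProcessPoint(2345.0, 17.0, 222.0)
        assert oracle.survival(p) == oracle.survival(p)

    def test_survival_bounded(self, oracle, space):
        from probitab.design import random_design
        smax = oracle.params.tolerance.s_max
        for p in random_design(space, 60, 21):
            s = oracle.survival(p)
            assert 0.0 < s <= smax + 1e-12

    def test_survival_monotone_in_main_pressure(self, oracle):
        mains = np.linspace(150.0, 400.0, 20)
        s = [oracle.survival(ProcessPoint(3000.0, 0.0, m)) for m in mains]
        assert (np.diff(s) <= 1e-12).all()

    def test_faster_compression_kills_more_at_high_pressure(self, oracle):
        slow = oracle.survival(ProcessPoint(500.0, 0.0, 400.0))
        fast = oracle.survival(ProcessPoint(5000.0, 0.0, 400.0))
        assert fast < slow

    def test_integrated_kinetics_mode_runs(self, calibration):
        params = dataclasses.replace(calibration.params,
                                     kinetics="integrated", D_crit_s=5.0)
        s = CompactionOracle(params).survival(ProcessPoint(4000.0, 0.0, 400.0))
        assert 0.0 < s <= 1.0


class TestCalibration:
    def test_reaches_all_anchors(self, calibration):
        assert calibration.converged
        for name, r in calibration.residuals.items():
            assert abs(r) < 1e-3, f"anchor {name} missed: residual {r}"

    def test_reproduces_shipped_parameters(self, calibration):
        shipped = default_params(calibrated=True)
        assert calibration.params.tolerance.T_crit == pytest.approx(
            shipped.tolerance.T_crit, rel=1e-6)
        assert calibration.params.tolerance.z_T == pytest.approx(
            shipped.tolerance.z_T, rel=1e-6)
        assert calibration.params.material.mu_fric == pytest.approx(
            shipped.material.mu_fric, rel=1e-6)
        assert calibration.params.material.h_punch == pytest.approx(
            shipped.material.h_punch, rel=1e-6)

    def test_fixed_point_of_shipped_parameters(self, calibration, oracle):
        # the shipped parameters already satisfy every anchor
        from probitab.oracle import _anchor_value
        for a in default_anchors():
            v = _anchor_value(oracle, a)
            if a.kind == "at_least":
                assert v >= a.target - 1e-6
            else:
                assert v == pytest.approx(a.target, rel=1e-3)

    def test_empty_anchor_set_rejected(self):
        with pytest.raises(ValueError):
            calibrate(anchors=[])

    def test_underdetermined_rejected(self):
        one = [Anchor("gentle", 0.99, "at_least",
                      (ProcessPoint(100.0, 20.0, 110.0),))]
        with pytest.raises(ValueError):
            calibrate(anchors=one, free=("T_crit", "z_T"))
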