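"""Inverse estimation: objective structure, passive-fit staging and
contractility recovery."""

import numpy as np
import pytest

from lvmech import (ActiveConfig, solve_diastole, solve_systole)
from lvmech.cohort import CohortConfig, generate_subject
from lvmech.inverse import (MeasurementSet, STRAIN_SCALE, VOLUME_SCALE_ML,
                            fit_contractility, fit_passive, objective)
from lvmech.geometry import N_SEGMENTS


def _meas_from_states(ed, es, seg_class, edp=8.0, sbp=144.6):
    return MeasurementSet(edv=ed.volume_ml, esv=es.volume_ml,
                          strains_dia=ed.strains, strains_sys=es.strains,
                          segment_class=seg_class, edp=edp, sbp=sbp)


class TestObjective:
    def test_perfect_match_scores_zero(self, ed_healthy, es_healthy, healthy_map):
        meas = _meas_from_states(ed_healthy, es_healthy, healthy_map.segment_class)
        assert objective(meas, ed_healthy) == pytest.approx(0.0, abs=1e-20)
        assert objective(meas, es_healthy) == pytest.approx(0.0, abs=1e-20)

    def test_single_strain_mismatch_weighting(self, ed_healthy, healthy_map):
        strains = ed_healthy.strains.copy()
        strains[5] += 0.01
        meas = MeasurementSet(edv=ed_healthy.volume_ml, esv=50.0,
                              strains_dia=strains, strains_sys=strains,
                              segment_class=healthy_map.segment_class,
                              edp=8.0, sbp=144.6)
        assert objective(meas, ed_healthy) == pytest.approx(
            (0.01 / STRAIN_SCALE) ** 2)

    def test_volume_mismatch_weighting(self, ed_healthy, healthy_map):
        meas = MeasurementSet(edv=ed_healthy.volume_ml + 5.0, esv=50.0,
                              strains_dia=ed_healthy.strains,
                              strains_sys=ed_healthy.strains,
                              segment_class=healthy_map.segment_class,
                              edp=8.0, sbp=144.6)
        assert objective(meas, ed_healthy) == pytest.approx(
            (5.0 / VOLUME_SCALE_ML) ** 2)

    def test_mi_mode_uses_remote_segments_only(self, ed_mi, es_mi, mi_map):
        meas = _meas_from_states(ed_mi, es_mi, mi_map.segment_class,
                                 edp=16.0, sbp=118.6)
        base = objective(meas, es_mi, mode="mi")
        # corrupting non-remote measured strains must not change the value
        corrupted = _meas_from_states(ed_mi, es_mi, mi_map.segment_class,
                                      edp=16.0, sbp=118.6)
        for i, c in enumerate(mi_map.segment_class):
            if c != "remote":
                corrupted.strains_sys[i] += 0.5
        assert objective(corrupted, es_mi, mode="mi") == pytest.approx(base)
        # the number of contributing strain terms equals the remote count
        n_remote = mi_map.n_remote
        uniform = _meas_from_states(ed_mi, es_mi, mi_map.segment_class,
                                    edp=16.0, sbp=118.6)
        uniform.strains_sys = es_mi.strains + 0.01
        uniform.esv = es_mi.volume_ml
        assert objective(uniform, es_mi, mode="mi") == pytest.approx(
            n_remote * (0.01 / STRAIN_SCALE) ** 2)

    def test_mi_mode_without_remote_segments_rejected(self, ed_healthy):
        meas = MeasurementSet(edv=100.0, esv=50.0, strains_dia=np.zeros(24),
                              strains_sys=np.zeros(24),
                              segment_class=["infarct"] * N_SEGMENTS,
                              edp=8.0, sbp=120.0)
        with pytest.raises(ValueError):
            objective(meas, ed_healthy, mode="mi")

    def test_unknown_mode_rejected(self, ed_healthy, healthy_map):
        meas = _meas_from_states(ed_healthy, ed_healthy, healthy_map.segment_class)
        with pytest.raises(ValueError):
            objective(meas, ed_healthy, mode="bogus")


class TestPassiveFit:
    def test_init_at_truth_converges_immediately(self, mesh, fibers, healthy_map,
                                                 p_healthy, ed_healthy):
        meas = _meas_from_states(ed_healthy, ed_healthy, healthy_map.segment_class)
        fit = fit_passive(meas, mesh, fibers, healthy_map, p_healthy,
                          polish_iters=15)
        assert fit.converged
        assert fit.objective_value < 1e-3
        assert fit.stiffness_scale == pytest.approx(1.0, abs=0.05)

    def test_fiber_direction_stiffness_recovered_from_biased_init(
            self, mesh, fibers, healthy_map, p_healthy, ed_healthy):
        from lvmech.constitutive import (Deformation, passive_cauchy_stress,
                                         fiber_stress)

        def fib_stiff(p):
            lam = 1.1
            d = Deformation(F=np.diag([lam, lam**-0.5, lam**-0.5]),
                            f0=[1, 0, 0], s0=[0, 1, 0])
            return fiber_stress(passive_cauchy_stress(p, d, 0.0), d)

        meas = _meas_from_states(ed_healthy, ed_healthy, healthy_map.segment_class)
        init = p_healthy.scaled(stiffness_scale=1.8, fiber_scale=0.6)
        fit = fit_passive(meas, mesh, fibers, healthy_map, init)
        # individual coefficients are non-identifiable; the fibre-direction
        # response is the robustly recoverable quantity
        assert fib_stiff(fit.params) == pytest.approx(fib_stiff(p_healthy),
                                                      rel=0.05)

    def test_declared_filling_pressure_drives_recovered_stiffness(
            self, mesh, fibers, healthy_map, p_healthy, ed_healthy):
        meas8 = _meas_from_states(ed_healthy, ed_healthy,
                                  healthy_map.segment_class, edp=8.0)
        meas16 = _meas_from_states(ed_healthy, ed_healthy,
                                   healthy_map.segment_class, edp=16.0)
        fit8 = fit_passive(meas8, mesh, fibers, healthy_map, p_healthy,
                           polish_iters=10)
        fit16 = fit_passive(meas16, mesh, fibers, healthy_map, p_healthy,
                            polish_iters=10)
        assert fit16.stiffness_scale > fit8.stiffness_scale


class TestContractilityFit:
    def test_zero_contractility_recovered(self, mesh, fibers, healthy_map,
                                          p_healthy):
        ed = solve_diastole(mesh, fibers, healthy_map, p_healthy, 8.0)
        es = solve_systole(mesh, fibers, healthy_map, p_healthy,
                           ActiveConfig(T_req=0.0), 20.0, ed)
        meas = _meas_from_states(ed, es, healthy_map.segment_class, sbp=20.0)
        fit = fit_contractility(meas, mesh, fibers, healthy_map, p_healthy)
        assert fit.T_req == pytest.approx(0.0, abs=1.0)

    def test_noisy_recovery_over_randomized_subjects(self):
        """1%-noise measurements; randomized true T_req in [100, 220] kPa."""
        cfg = CohortConfig.default()
        rng = np.random.default_rng(2024)
        errors = []
        subj = generate_subject(cfg, "healthy", seed=7, noise=0.0,
                                t_req=150.0, sbp=140.0, edv_target=125.0)
        ed = solve_diastole(subj.mesh, subj.fibers, subj.infarct,
                            subj.passive_params, 8.0)
        for _ in range(8):
            t_true = float(rng.uniform(100.0, 220.0))
            es = solve_systole(subj.mesh, subj.fibers, subj.infarct,
                               subj.passive_params,
                               ActiveConfig(T_req=t_true), 140.0, ed)
            meas = MeasurementSet(
                edv=subj.measurements.edv * (1 + 0.01 * rng.standard_normal()),
                esv=es.volume_ml * (1 + 0.01 * rng.standard_normal()),
                strains_dia=subj.measurements.strains_dia,
                strains_sys=es.strains * (1 + 0.01 * rng.standard_normal(24)),
                segment_class=subj.infarct.segment_class, edp=8.0, sbp=140.0)
            fit = fit_contractility(meas, subj.mesh, subj.fibers, subj.infarct,
                                    subj.passive_params, xatol=0.5)
            errors.append(abs(fit.T_req - t_true))
        assert np.median(errors) < 5.0

    def test_objective_minimized_at_generating_truth(self, mesh, fibers,
                                                     healthy_map, p_healthy,
                                                     ed_healthy, es_healthy):
        meas = _meas_from_states(ed_healthy, es_healthy, healthy_map.segment_class)
        fit = fit_contractility(meas, mesh, fibers, healthy_map, p_healthy)
        probes = [v for t, v in fit.trace if abs(t - 157.0) > 5.0]
        assert fit.objective_value <= min(probes)
        assert fit.converged
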