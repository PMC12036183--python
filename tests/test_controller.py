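import numpy as np
import pytest

from microext import (
    ExperimentConfig,
    MechanicalParams,
    SpecimenGeometry,
    StopFlag,
    cross_section_area,
    manual_step,
    run_creep,
    run_ramp,
)
from microext.errors import ConfigError

from conftest import make_bench, quiet_sensor


def slow_sls(tau_s=20.0):
    """Elastic SLS with a long retardation time for clean limit checks."""
    return MechanicalParams(E_inf_MPa=300.0, E_1_MPa=150.0, tau_s=tau_s)


class TestConfig:
    def test_zero_distance_rejected(self):
        with pytest.raises(ConfigError):
            ExperimentConfig(distance_um=0.0)

    def test_step_count_is_ceiling_of_distance_over_step(self):
        assert ExperimentConfig(distance_um=250.0, step_size_um=5.0).n_steps == 50
        assert ExperimentConfig(distance_um=251.0, step_size_um=5.0).n_steps == 51

    def test_negative_wait_other_than_trigger_sentinel_rejected(self):
        with pytest.raises(ConfigError):
            ExperimentConfig(wait_time_s=-2.0)


class TestRamp:
    def test_fifty_step_ramp_logs_fifty_exact_positions(self, cyl_geom):
        bench = make_bench(cyl_geom, slow_sls())
        sensor = quiet_sensor(bench)
        config = ExperimentConfig(distance_um=250.0, step_size_um=5.0,
                                  wait_time_s=0.0, n_force_samples=1,
                                  snapshots=False)
        log = run_ramp(config, bench, sensor)
        assert len(log.records) == 50
        assert log.status == "completed"
        for k, rec in enumerate(log.records, start=1):
            assert rec.position_nm == k * 5.0 * 1e3
        times = [r.time_us for r in log.records]
        assert all(b > a for a, b in zip(times, times[1:]))
        # completed runs return the actuator to its start
        assert bench.actuator.position_steps == 0

    def test_travel_limit_checked_before_first_step(self, cyl_geom):
        from microext import ActuatorSpec, VirtualBench

        bench = make_bench(cyl_geom, slow_sls())
        bench.actuator.spec = ActuatorSpec(travel_limit_um=100.0)
        sensor = quiet_sensor(bench)
        config = ExperimentConfig(distance_um=250.0, step_size_um=5.0,
                                  snapshots=False)
        with pytest.raises(ConfigError):
            run_ramp(config, bench, sensor)
        assert bench.actuator.position_steps == 0

    def test_rupture_mid_run_zeroes_forces_and_reports(self, cyl_geom):
        params = MechanicalParams(E_inf_MPa=300.0, E_1_MPa=150.0, tau_s=2.0,
                                  sigma_ult_MPa=1.0)
        bench = make_bench(cyl_geom, params)
        sensor = quiet_sensor(bench)
        config = ExperimentConfig(distance_um=50.0, step_size_um=5.0,
                                  wait_time_s=1.0, n_force_samples=1,
                                  snapshots=False)
        log = run_ramp(config, bench, sensor)
        assert log.status == "ruptured"
        forces = np.array([r.force_uN for r in log.records])
        assert forces.max() > 0
        assert forces[-1] == pytest.approx(0.0, abs=1e-9)

    def test_stop_flag_keeps_partial_log_and_position(self, cyl_geom):
        bench = make_bench(cyl_geom, slow_sls())
        sensor = quiet_sensor(bench)
        config = ExperimentConfig(distance_um=250.0, step_size_um=5.0,
                                  wait_time_s=0.0, n_force_samples=1,
                                  snapshots=False)
        stop = StopFlag()

        def maybe_stop(rec):
            if rec.step_index == 10:
                stop.set()

        log = run_ramp(config, bench, sensor, stop=stop, on_step=maybe_stop)
        assert log.status == "stopped"
        assert len(log.records) == 10
        # actuator NOT auto-returned after a stop; manual return works
        assert bench.actuator.position_um == pytest.approx(50.0)
        bench.actuator.move_steps(-bench.actuator.position_steps)
        assert bench.actuator.position_nm == 0.0

    def test_manual_steps_reproduce_ramp_schedule(self, cyl_geom):
        params = slow_sls(tau_s=5.0)
        config = ExperimentConfig(distance_um=25.0, step_size_um=5.0,
                                  wait_time_s=1.0, n_force_samples=3,
                                  snapshots=False)
        bench_a = make_bench(cyl_geom, params, seed=3)
        log = run_ramp(config, bench_a, quiet_sensor(bench_a))
        bench_b = make_bench(cyl_geom, params, seed=3)
        sensor_b = quiet_sensor(bench_b)
        manual = [
            manual_step(bench_b, sensor_b, 5.0, wait_time_s=1.0,
                        n_force_samples=3, snapshot=False, step_index=k)
            for k in range(1, 6)
        ]
        for auto, man in zip(log.records, manual):
            assert man.position_nm == auto.position_nm
            assert man.force_uN == pytest.approx(auto.force_uN, rel=1e-12)
            assert man.time_us == auto.time_us

    def test_external_trigger_mode_matches_zero_wait_log(self, cyl_geom):
        params = slow_sls(tau_s=5.0)
        bench_a = make_bench(cyl_geom, params, seed=5)
        log_a = run_ramp(
            ExperimentConfig(distance_um=25.0, step_size_um=5.0,
                             wait_time_s=0.0, n_force_samples=1,
                             snapshots=False),
            bench_a, quiet_sensor(bench_a))
        confirmed = []
        bench_b = make_bench(cyl_geom, params, seed=5)
        log_b = run_ramp(
            ExperimentConfig(distance_um=25.0, step_size_um=5.0,
                             wait_time_s=-1, n_force_samples=1,
                             snapshots=False),
            bench_b, quiet_sensor(bench_b), confirm=confirmed.append)
        assert confirmed == [1, 2, 3, 4, 5]
        assert [r.force_uN for r in log_b.records] == [
            r.force_uN for r in log_a.records]

    def test_wait_time_selects_equilibrium_or_glassy_stiffness(self, cyl_geom):
        """Long waits relax each step fully (slope E_inf*A/L0); short waits
        probe the instantaneous modulus ((E_inf+E_1)*A/L0)."""
        params = slow_sls(tau_s=20.0)
        A = cross_section_area(cyl_geom)
        L0 = cyl_geom.gauge_length_um

        bench = make_bench(cyl_geom, params)
        log = run_ramp(
            ExperimentConfig(distance_um=50.0, step_size_um=5.0,
                             wait_time_s=200.0, n_force_samples=1,
                             snapshots=False),
            bench, quiet_sensor(bench))
        forces = np.array([r.force_uN for r in log.records])
        inc = np.diff(forces)[3:]
        assert inc.mean() / 5.0 == pytest.approx(params.E_inf_MPa * A / L0,
                                                 rel=0.02)

        bench = make_bench(cyl_geom, params)
        log = run_ramp(
            ExperimentConfig(distance_um=50.0, step_size_um=5.0,
                             wait_time_s=0.0, n_force_samples=1,
                             snapshots=False),
            bench, quiet_sensor(bench))
        forces = np.array([r.force_uN for r in log.records])
        inc = np.diff(forces)[:3]
        glassy = params.E_inf_MPa + params.E_1_MPa
        assert inc.mean() / 5.0 == pytest.approx(glassy * A / L0, rel=0.02)


class TestCreep:
    def _creep_setup(self, with_slip=False, noise=0.0, seed=0):
        from microext.presets import creep_test_specimen

        geom, params = creep_test_specimen(with_slip=with_slip)
        bench = make_bench(geom, params, microstep_divisor=32,
                           noise_sd_units=noise, seed=seed)
        return geom, params, bench

    def test_zero_threshold_delegates_to_ramp(self):
        geom, params, bench = self._creep_setup()
        config = ExperimentConfig(mode="creep", distance_um=25.0,
                                  step_size_um=0.15625, wait_time_s=0.0,
                                  creep_threshold_uN=0.0, n_force_samples=1,
                                  snapshots=False)
        log = run_creep(config, bench, quiet_sensor(bench))
        assert len(log.records) == config.n_steps
        assert log.records[-1].position_nm == pytest.approx(25_000.0)

    def test_threshold_above_capacity_rejected(self):
        geom, params, bench = self._creep_setup()
        config = ExperimentConfig(mode="creep", distance_um=100.0,
                                  step_size_um=0.15625,
                                  creep_threshold_uN=2e6, snapshots=False)
        with pytest.raises(ConfigError):
            run_creep(config, bench, quiet_sensor(bench))

    def test_force_held_within_deadband_after_reach(self):
        geom, params, bench = self._creep_setup(noise=0.01, seed=9)
        threshold = 5000.0
        config = ExperimentConfig(
            mode="creep", distance_um=100.0, step_size_um=0.15625,
            creep_threshold_uN=threshold, approach_rate_um_per_s=2.0,
            max_duration_s=60.0, n_force_samples=4, snapshots=False)
        log = run_creep(config, bench, quiet_sensor(bench))
        assert log.status == "completed"
        reached = np.nonzero(
            np.array([r.force_uN for r in log.records]) >= threshold)[0][0]
        hold = np.array([r.force_uN for r in log.records[reached + 1:]])
        assert hold.size >= 30
        in_band = np.abs(hold - threshold) <= config.creep_deadband_frac * threshold
        assert in_band.mean() >= 0.95
        # never beyond threshold + one-step force increment + noise
        A = cross_section_area(geom)
        step_force = ((params.E_inf_MPa + params.E_1_MPa) * A
                      * config.step_size_um / geom.gauge_length_um)
        assert hold.max() <= threshold + step_force + 30.0
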