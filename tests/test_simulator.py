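import dataclasses

import numpy as np
import pytest

import bicoid2d as b
from bicoid2d import ConcentrationField, DevelopmentalSchedule, ModelParams, SourceSpec
from bicoid2d.simulate import run, step


def homogeneous_schedule():
    """Schedule with no cortical layer, so the medium never changes."""
    return DevelopmentalSchedule(cortical_thickness_um=0.0)


def make_field(geom, values, t_s=0.0):
    B = np.where(geom.mask, values, 0.0)
    return ConcentrationField(B_tot=B, t_s=t_s, cycle=9)


def total_mass(field, geom):
    return field.B_tot.sum() * geom.cube_volume


class TestStepKernel:
    def test_uniform_field_is_stationary(self, strip_geom):
        params = ModelParams(omega=0.0)
        sched = homogeneous_schedule()
        f = make_field(strip_geom, 1.0)
        src = np.zeros(strip_geom.shape)
        for _ in range(10):
            f = step(f, strip_geom, sched, params, src)
        assert np.allclose(f.B_tot[strip_geom.mask], 1.0, rtol=1e-12)

    def test_mass_conserved_without_sources_or_decay(self, main_geom):
        params = ModelParams(omega=0.0)
        sched = homogeneous_schedule()
        rng = np.random.default_rng(0)
        f = make_field(main_geom, rng.uniform(0, 1, main_geom.shape))
        m0 = total_mass(f, main_geom)
        src = np.zeros(main_geom.shape)
        for _ in range(400):
            f = step(f, main_geom, sched, params, src)
        assert abs(total_mass(f, main_geom) - m0) <= 1e-9 * m0

    def test_pure_decay_is_geometric(self, strip_geom):
        omega = 1e-3
        params = ModelParams(omega=omega)
        sched = homogeneous_schedule()
        rng = np.random.default_rng(1)
        f = make_field(strip_geom, rng.uniform(0.5, 1.5, strip_geom.shape))
        m0 = total_mass(f, strip_geom)
        src = np.zeros(strip_geom.shape)
        n = 200
        for _ in range(n):
            f = step(f, strip_geom, sched, params, src)
        assert total_mass(f, strip_geom) == pytest.approx(
            m0 * (1 - omega * params.dt) ** n, rel=1e-12
        )

    def test_production_adds_exact_mass(self, main_geom):
        params = ModelParams(omega=0.0)
        sched = homogeneous_schedule()
        src = b.build_source(main_geom, SourceSpec(aggregate_J=2.0), cycle=5)
        f = make_field(main_geom, 0.0)
        n = 150
        for _ in range(n):
            f = step(f, main_geom, sched, params, src)
        assert total_mass(f, main_geom) == pytest.approx(2.0 * n * params.dt, rel=1e-12)

    def test_field_linear_in_production(self, main_geom):
        params = ModelParams()
        sched = homogeneous_schedule()
        fields = []
        for J in (1.0, 2.0):
            src = b.build_source(main_geom, SourceSpec(aggregate_J=J), cycle=5)
            f = make_field(main_geom, 0.0)
            for _ in range(100):
                f = step(f, main_geom, sched, params, src)
            fields.append(f.B_tot)
        assert np.allclose(fields[1], 2 * fields[0], rtol=1e-12)


class TestSteadyStateShape:
    def test_point_source_strip_approaches_exponential(self, strip_geom):
        # 1-D synthesis-diffusion-degradation: C(x) ~ exp(-x/lambda),
        # lambda = sqrt(D/omega) in the homogeneous medium
        D, omega = 2.0, 2e-3
        params = ModelParams(D=D, omega=omega)
        sched = homogeneous_schedule()
        src = np.zeros(strip_geom.shape)
        src[0, 0] = 1.0
        f = make_field(strip_geom, 0.0)
        for _ in range(15000):  # 3000 s = 6 lifetimes
            f = step(f, strip_geom, sched, params, src)
        prof = b.APProfile(
            x=strip_geom.xc,
            xfrac=strip_geom.xc / strip_geom.L,
            value=f.B_tot[0],
            cycle=14,
            t_s=f.t_s,
        )
        fit = b.fit_exponential(prof, region=(0.05, 0.35))
        assert fit.lam == pytest.approx(np.sqrt(D / omega), rel=0.02)
        assert fit.adj_r2 > 0.999


class TestRun:
    def test_snapshots_cover_cycles_10_to_14(self, main_run):
        assert main_run.cycles == [10, 11, 12, 13, 14]
        times = [s.t_min for s in main_run.snapshots]
        assert times == [94, 109, 124, 139, 154]

    def test_field_nonnegative_inside_zero_outside(self, main_run):
        geom = main_run.geom
        for s in main_run.snapshots:
            assert np.all(s.B_tot[geom.mask] >= 0)
            assert np.all(s.B_tot[~geom.mask] == 0)

    def test_profile_decreases_beyond_source(self, main_run, main_config):
        f = main_run.at_cycle(14)
        prof = b.extract_profile(
            f, main_run.geom, main_config.schedule, main_config.params, "bound"
        )
        # peak is near the source disc center, not at the pole
        peak_x = prof.x[np.argmax(prof.value)]
        assert 0 < peak_x < 100
        tail = prof.value[prof.x > 120]
        assert np.all(np.diff(tail) < 0)

    def test_rerun_is_bitwise_deterministic(self, main_run, main_config):
        again = run(main_config)
        for s1, s2 in zip(main_run.snapshots, again.snapshots):
            assert np.array_equal(s1.B_tot, s2.B_tot)

    def test_lambda_consistent_across_resolutions(self, main_run, main_config):
        rep5 = b.evaluate_criteria(main_run)
        cfg2 = dataclasses.replace(
            main_config, params=dataclasses.replace(main_config.params, dx=2.0)
        )
        rep2 = b.evaluate_criteria(run(cfg2))
        assert rep2.lam == pytest.approx(rep5.lam, rel=0.05)
        assert rep2.ratio == pytest.approx(rep5.ratio, rel=0.05)
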