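import numpy as np
import pytest

import bicoid2d as b
from bicoid2d import APProfile, ConcentrationField
from bicoid2d.analysis import _adjusted_r2


def flat_field(geom, value, cycle, sched):
    t_s = sched.sample_times_s[cycle - 10]
    B = np.where(geom.mask, value, 0.0)
    return ConcentrationField(B_tot=B, t_s=t_s, cycle=cycle)


class TestExtractProfile:
    def test_uniform_field_gives_flat_bound_profile(self, main_geom, main_config):
        sched, params = main_config.schedule, main_config.params
        f = flat_field(main_geom, 1.0, 14, sched)
        prof = b.extract_profile(f, main_geom, sched, params, "bound")
        # bound fraction at cycle 14: K_A*S / (1 + K_A*S) with K_A*S = 2.4
        assert np.allclose(prof.value, 2.4 / 3.4, atol=1e-12)
        tot = b.extract_profile(f, main_geom, sched, params, "total")
        assert np.allclose(tot.value, 1.0)

    def test_nuclear_pool_scales_bound_by_nuclei(self, main_geom, main_config):
        sched, params = main_config.schedule, main_config.params
        f = flat_field(main_geom, 1.0, 14, sched)
        bound = b.extract_profile(f, main_geom, sched, params, "bound")
        nuc = b.extract_profile(f, main_geom, sched, params, "nuclear")
        assert np.allclose(nuc.value, bound.value / 8192)

    def test_pre_cortical_snapshot_rejected(self, main_geom, main_config):
        f = ConcentrationField(
            B_tot=np.where(main_geom.mask, 1.0, 0.0), t_s=60.0, cycle=9
        )
        with pytest.raises(ValueError):
            b.extract_profile(f, main_geom, main_config.schedule, main_config.params)


class TestFitExponential:
    def test_recovers_exact_exponential(self):
        prof = b.synthetic_profile(lam=100.0, amplitude=7.0)
        fit = b.fit_exponential(prof, region=(0.0, 1.0))
        assert fit.lam == pytest.approx(100.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(7.0, rel=1e-6)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_matches_grid_search_on_noisy_profile(self):
        prof = b.synthetic_profile(lam=92.0, amplitude=5.0, noise_sd=0.05, seed=7)
        fit = b.fit_exponential(prof, region=(0.2, 0.7))
        # independent brute-force minimiser over (A, lam)
        sel = (prof.xfrac >= 0.2) & (prof.xfrac <= 0.7)
        x, y = prof.x[sel], prof.value[sel]
        lams = np.linspace(60, 130, 1401)
        best = None
        for lam in lams:
            basis = np.exp(-x / lam)
            A = (basis @ y) / (basis @ basis)  # optimal amplitude, closed form
            sse = ((y - A * basis) ** 2).sum()
            if best is None or sse < best[1]:
                best = (lam, sse)
        assert fit.lam == pytest.approx(best[0], rel=0.02)

    @pytest.mark.parametrize("scale", [0.1, 1.0, 250.0])
    def test_scale_equivariance(self, scale):
        prof = b.synthetic_profile(lam=80.0, amplitude=3.0, noise_sd=0.03, seed=3)
        ref = b.fit_exponential(prof)
        scaled = APProfile(
            x=prof.x, xfrac=prof.xfrac, value=prof.value * scale,
            cycle=prof.cycle, t_s=prof.t_s,
        )
        fit = b.fit_exponential(scaled)
        assert fit.lam == pytest.approx(ref.lam, rel=1e-9)
        assert fit.adj_r2 == pytest.approx(ref.adj_r2, abs=1e-12)

    def test_too_few_points_rejected(self):
        prof = b.synthetic_profile(lam=100.0, n_points=20)
        with pytest.raises(ValueError):
            b.fit_exponential(prof, region=(0.2, 0.25))

    def test_adjusted_r2_penalises_parameters(self):
        y = np.array([3.0, 2.1, 1.4, 1.05, 0.7, 0.52])
        y_hat = y + np.array([0.05, -0.02, 0.03, -0.04, 0.01, -0.02])
        n = len(y)
        r2 = 1 - ((y - y_hat) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert _adjusted_r2(y, y_hat, p=2) == pytest.approx(
            1 - (1 - r2) * (n - 1) / (n - 3)
        )
        assert _adjusted_r2(y, y_hat, p=2) < r2


class TestStabilityG:
    @staticmethod
    def profiles_with_ratio(r):
        base = b.synthetic_profile(lam=90.0, amplitude=2.0)
        return {
            c: APProfile(
                x=base.x, xfrac=base.xfrac, value=base.value * r ** (c - 10),
                cycle=c, t_s=0.0,
            )
            for c in range(10, 15)
        }

    def test_identical_profiles_give_zero(self):
        assert b.stability_g(self.profiles_with_ratio(1.0)) == pytest.approx(0.0)

    @pytest.mark.parametrize("r", [1.05, 0.9])
    def test_geometric_growth_recovers_ratio(self, r):
        assert b.stability_g(self.profiles_with_ratio(r)) == pytest.approx(r - 1)

    def test_needs_two_cycles(self):
        profs = self.profiles_with_ratio(1.0)
        with pytest.raises(ValueError):
            b.stability_g({10: profs[10]})

    def test_misaligned_grids_rejected(self):
        profs = self.profiles_with_ratio(1.0)
        p = profs[11]
        profs[11] = APProfile(
            x=p.x + 1.0, xfrac=p.xfrac, value=p.value, cycle=11, t_s=0.0
        )
        with pytest.raises(ValueError):
            b.stability_g(profs)


class TestCorticalRatio:
    def test_uniform_field_gives_count_ratio(self, main_geom, main_config):
        sched = main_config.schedule
        f = flat_field(main_geom, 1.0, 14, sched)
        status = b.region_status(main_geom, 14, 30.0)
        expected = (status == b.CORTICAL).sum() / (status == b.INNER).sum()
        assert b.cortical_ratio(f, main_geom, sched) == pytest.approx(expected)

    def test_pre_cortical_cycle_rejected(self, main_geom, main_config):
        f = ConcentrationField(
            B_tot=np.where(main_geom.mask, 1.0, 0.0), t_s=60.0, cycle=9
        )
        with pytest.raises(ValueError):
            b.cortical_ratio(f, main_geom, main_config.schedule)


class TestEnsembleNoise:
    def test_identical_embryos_have_zero_noise(self):
        profs = [b.synthetic_profile(lam=90.0) for _ in range(5)]
        df = b.ensemble_noise(profs, axis="xfrac", n_boot=50, seed=0)
        assert np.allclose(df["noise"], 0.0)

    def test_perfectly_scaling_ensemble_prefers_fractional_axis(self):
        # lambda proportional to L: profiles collapse exactly in x/L
        rng = np.random.default_rng(2)
        profs = [
            b.synthetic_profile(lam=0.16 * L, amplitude=2.0, L=L)
            for L in rng.normal(550, 20, 12)
        ]
        cmp = b.noise_comparison(profs, L_mean=550.0, n_boot=50, seed=0)
        assert cmp["mid_noise_xfrac"] == pytest.approx(0.0, abs=1e-12)
        assert cmp["mid_noise_x"] > 0.01

    def test_size_independent_profiles_prefer_absolute_axis(self):
        # same lambda and amplitude in absolute x for every embryo
        rng = np.random.default_rng(3)
        profs = [
            b.synthetic_profile(lam=90.0, amplitude=2.0, L=L)
            for L in rng.normal(550, 20, 12)
        ]
        cmp = b.noise_comparison(profs, L_mean=550.0, n_boot=50, seed=0)
        # not exactly zero: each embryo is tabulated on its own x grid
        assert cmp["mid_noise_x"] == pytest.approx(0.0, abs=1e-3)
        assert cmp["mid_noise_xfrac"] > 10 * cmp["mid_noise_x"]

    def test_needs_two_embryos(self):
        with pytest.raises(ValueError):
            b.ensemble_noise([b.synthetic_profile(lam=90.0)])
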