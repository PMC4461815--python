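"""Observer statistics, density models and decision rules."""

import math
import warnings

import numpy as np
import pytest
from scipy import integrate, stats

from ordertex.observers import (
    ChannelEnergyObserver,
    DensityModel,
    GaborSpec,
    QuadrantStatistic,
    analytic_ideal_decide,
    channel_energy_map,
    decide_4afc,
    energy_from_pair_statistic,
    fit_density,
    fit_density_pair,
    gabor_kernels,
    luminance_statistic,
    pair_statistic,
    published_gabor_table,
    quadrant_energy,
)
from ordertex.render_io import RenderSpec, render_texture
from ordertex.sampler import make_distractor
from ordertex.texture_model import energy


class TestCountStatistics:
    def test_uniform_lattice_luminance_counts(self):
        stat = luminance_statistic(np.zeros((32, 32), dtype=int))
        np.testing.assert_array_equal(stat.values, [1024, 0, 0])

    def test_permuted_distractor_has_identical_luminance(self, potts, rng):
        target = rng.integers(0, 3, size=(32, 32))
        d = make_distractor(potts, "permuted", rng, target=target)
        np.testing.assert_array_equal(
            luminance_statistic(d).values, luminance_statistic(target).values
        )

    def test_luminance_invariant_under_rearrangement(self, rng):
        lat = rng.integers(0, 3, size=(8, 8))
        shuffled = rng.permutation(lat.ravel()).reshape(8, 8)
        np.testing.assert_array_equal(
            luminance_statistic(lat).values, luminance_statistic(shuffled).values
        )

    def test_all_zero_pair_counts(self, potts):
        stat = pair_statistic(np.zeros((32, 32), dtype=int), potts)
        expected = np.zeros(18)
        expected[0] = 1024  # joint (0,0) for offset (0,1)
        expected[9] = 1024  # joint (0,0) for offset (1,0)
        np.testing.assert_array_equal(stat.values, expected)

    def test_pair_counts_match_brute_force(self, potts4, rng):
        lat = rng.integers(0, 3, size=(4, 4))
        stat = pair_statistic(lat, potts4).values
        brute = np.zeros((2, 3, 3))
        for i, (dy, dx) in enumerate(potts4.offsets):
            for p in range(4):
                for q in range(4):
                    brute[i, lat[p, q], lat[(p + dy) % 4, (q + dx) % 4]] += 1
        np.testing.assert_array_equal(stat, brute.reshape(-1))

    def test_energy_is_linear_in_pair_counts(self, potts, rng):
        lat = rng.integers(0, 3, size=(32, 32))
        stat = pair_statistic(lat, potts).values
        assert energy_from_pair_statistic(stat, potts) == pytest.approx(energy(lat, potts))


def _grating(theta_deg, freq_cpd, pixel_scale, side, phase=0.0):
    c = (side - 1) / 2
    y, x = np.mgrid[0:side, 0:side].astype(float)
    x = (x - c) / pixel_scale
    y = (y - c) / pixel_scale
    th = math.radians(theta_deg)
    return np.cos(2 * np.pi * freq_cpd * (x * math.cos(th) + y * math.sin(th)) + phase)


class TestChannelEnergy:
    # published set-1 filter parameters
    G1 = GaborSpec(sigma=0.085, theta=22.5, freq=6.87, pixel_scale=120.0)

    def test_zero_image_gives_zero_map(self):
        M = channel_energy_map(np.zeros((128, 128)), self.G1)
        np.testing.assert_array_equal(M, 0.0)

    def test_odd_kernel_has_zero_dc(self):
        _, odd = gabor_kernels(self.G1)
        assert abs(odd.sum()) < 1e-10

    def test_matched_grating_energy_is_uniform_in_interior(self):
        img = _grating(22.5, 6.87, 120.0, 256, phase=0.9)
        M = channel_energy_map(img, self.G1)
        margin = 64  # > 3 sigma plus kernel support
        interior = M[margin:-margin, margin:-margin]
        assert interior.min() > 0
        assert (interior.max() - interior.min()) / interior.mean() < 0.01

    def test_matched_vs_orthogonal_grating_ratio_exceeds_ten(self):
        matched = _grating(22.5, 6.87, 120.0, 256)
        ortho = _grating(112.5, 6.87, 120.0, 256)
        m = channel_energy_map(matched, self.G1)[64:-64, 64:-64].sum()
        o = channel_energy_map(ortho, self.G1)[64:-64, 64:-64].sum()
        assert m / o > 10

    def test_energy_invariant_under_joint_rotation(self, rng):
        img = rng.normal(size=(128, 128))
        g90 = GaborSpec(sigma=0.085, theta=112.5, freq=6.87, pixel_scale=120.0)
        e = channel_energy_map(img, self.G1).sum()
        e_rot = channel_energy_map(np.rot90(img), g90).sum()
        assert e_rot == pytest.approx(e, rel=1e-6)

    def test_quadrant_energy_properties(self, rng):
        img = np.zeros((128, 128))
        for q in range(4):
            assert quadrant_energy(img, q, self.G1) == 0.0
        tex = rng.normal(size=(64, 64))
        same = np.block([[tex, tex], [tex, tex]])
        es = [quadrant_energy(same, q, self.G1) for q in range(4)]
        np.testing.assert_allclose(es, es[0])
        # swapping two quadrant textures swaps their energies
        a, b = rng.normal(size=(64, 64)), 2 * rng.normal(size=(64, 64))
        d1 = np.block([[a, b], [tex, tex]])
        d2 = np.block([[b, a], [tex, tex]])
        assert quadrant_energy(d1, 0, self.G1) == pytest.approx(quadrant_energy(d2, 1, self.G1))
        assert quadrant_energy(d1, 1, self.G1) == pytest.approx(quadrant_energy(d2, 0, self.G1))

    def test_plan_matches_direct_render_pipeline(self, potts, rng):
        r = RenderSpec(pixel_scale=80.0)
        obs = ChannelEnergyObserver(potts, render=r)
        lats = rng.integers(0, 3, size=(2, 32, 32))
        fast = obs.statistics(lats)[:, 0]
        for i in range(2):
            img = render_texture(lats[i], potts, r)
            g = GaborSpec(obs.gabor.sigma, obs.gabor.theta, obs.gabor.freq, r.pixel_scale)
            direct = channel_energy_map(img, g).sum()
            # the plan runs in float32; ~1e-5 relative agreement expected
            assert fast[i] == pytest.approx(direct, rel=1e-4)

    def test_published_parameter_table_loads(self):
        table = published_gabor_table()
        assert len(table) == 10
        assert table[1].sigma == 0.085 and table[1].theta == 22.5 and table[1].freq == 6.87
        assert table[4].sigma == 0.123 and table[4].freq == 6.61


class TestDensityModels:
    def test_kde_recovers_standard_normal_density_at_zero(self, rng):
        model = fit_density(rng.normal(size=10000), kind="kde")
        true = 1 / math.sqrt(2 * math.pi)
        assert model.pdf(np.array([[0.0]]))[0] == pytest.approx(true, rel=0.10)

    def test_kde_matches_scipy_reference_in_one_dim(self, rng):
        # same Scott bandwidth rule: the two estimators should agree closely
        x = rng.normal(size=500)
        model = fit_density(x, kind="kde")
        ref = stats.gaussian_kde(x)  # scott, 1-d: sigma * n^(-1/5)
        grid = np.linspace(-3, 3, 21)[:, None]
        np.testing.assert_allclose(model.pdf(grid), ref(grid.T[0]), rtol=0.05)

    @pytest.mark.parametrize("dim", [1, 2])
    def test_kde_integrates_to_one(self, rng, dim):
        model = fit_density(rng.normal(size=(400, dim)), kind="kde")
        if dim == 1:
            val, _ = integrate.quad(lambda x: model.pdf(np.array([[x]]))[0], -8, 8)
        else:
            g = np.linspace(-7, 7, 141)
            xx, yy = np.meshgrid(g, g)
            pts = np.column_stack([xx.ravel(), yy.ravel()])
            val = model.pdf(pts).sum() * (g[1] - g[0]) ** 2
        assert val == pytest.approx(1.0, abs=0.01)

    def test_constant_samples_warn_and_stay_finite(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_density(np.full(50, 3.0), kind="kde")
        at_value = model.logpdf(np.array([[3.0]]))[0]
        away = model.logpdf(np.array([[4.0]]))[0]
        assert np.isfinite(at_value) and at_value > away

    def test_gaussian_moment_fit(self, rng):
        x = rng.normal(loc=2.0, scale=0.5, size=5000)
        model = fit_density(x, kind="gaussian")
        assert model.mean[0] == pytest.approx(2.0, abs=0.05)
        assert model.sd[0] == pytest.approx(0.5, abs=0.05)

    def test_whitened_pair_handles_degenerate_count_dimensions(self, rng):
        # counts with a fixed sum: the sum direction must be projected out
        a = rng.multinomial(100, [0.5, 0.3, 0.2], size=300).astype(float)
        b = rng.multinomial(100, [1 / 3] * 3, size=300).astype(float)
        ta, tb = fit_density_pair(a, b, kind="kde_whitened")
        assert ta.data.shape[1] == 2  # rank after removing the sum constraint
        scores = ta.logpdf(a[:50]) - tb.logpdf(a[:50])
        assert np.isfinite(scores).all()
        assert scores.mean() > 0  # class-a points look more like class a

    def test_json_round_trip(self, rng):
        for kind in ["kde", "gaussian"]:
            model = fit_density(rng.normal(size=(100, 2)), kind=kind)
            back = DensityModel.from_json(model.to_json())
            pts = rng.normal(size=(20, 2))
            np.testing.assert_allclose(back.logpdf(pts), model.logpdf(pts))
        ta, _ = fit_density_pair(
            rng.normal(size=(100, 3)), rng.normal(size=(100, 3)), kind="kde_whitened"
        )
        back = DensityModel.from_json(ta.to_json())
        pts = rng.normal(size=(20, 3))
        np.testing.assert_allclose(back.logpdf(pts), ta.logpdf(pts))


class TestDecisionRules:
    def _gauss(self, mean, sd=1.0):
        return DensityModel(
            kind="gaussian", training_n=1, dim=1,
            mean=np.array([mean]), sd=np.array([sd]),
        )

    def test_identical_densities_give_chance(self, rng):
        f = self._gauss(0.0)
        correct = 0
        n = 4000
        for _ in range(n):
            x = rng.normal(size=(4, 1))
            tq = rng.integers(4)
            correct += decide_4afc(x, f, f, rng) == tq
        se = math.sqrt(0.25 * 0.75 / n)
        assert correct / n == pytest.approx(0.25, abs=3 * se)

    def test_disjoint_supports_always_correct(self, rng):
        ft = self._gauss(100.0, 0.1)
        fd = self._gauss(0.0, 0.1)
        for _ in range(50):
            tq = rng.integers(4)
            x = np.zeros((4, 1))
            x[tq, 0] = 100.0
            assert decide_4afc(x, ft, fd, rng) == tq

    @pytest.mark.parametrize("dprime", [0.5, 1.5])
    def test_simulated_accuracy_matches_mafc_integral(self, rng, dprime):
        # P(correct) = ∫ φ(x − d') Φ(x)^3 dx for the max rule in 4AFC
        expected, _ = integrate.quad(
            lambda x: stats.norm.pdf(x - dprime) * stats.norm.cdf(x) ** 3, -10, 10
        )
        ft, fd = self._gauss(dprime), self._gauss(0.0)
        n = 4000
        correct = 0
        for _ in range(n):
            tq = rng.integers(4)
            x = rng.normal(size=(4, 1))
            x[tq, 0] += dprime
            correct += decide_4afc(x, ft, fd, rng) == tq
        se = math.sqrt(expected * (1 - expected) / n)
        assert correct / n == pytest.approx(expected, abs=3.5 * se)

    def test_mixed_statistic_kinds_rejected(self, rng):
        f = self._gauss(0.0)
        stats4 = [QuadrantStatistic("order", [0.1])] * 3 + [QuadrantStatistic("luminance", [0.1])]
        with pytest.raises(ValueError, match="mixed"):
            decide_4afc(stats4, f, f, rng)

    def test_analytic_ideal_prefers_ground_state(self, potts, rng):
        spec = potts.with_shape((16, 16))
        target = np.zeros((16, 16), dtype=int)
        wins = 0
        for _ in range(50):
            configs = [rng.integers(0, 3, size=(16, 16)) for _ in range(4)]
            tq = rng.integers(4)
            configs[tq] = target
            wins += analytic_ideal_decide(configs, spec, 0.5, rng) == tq
        assert wins == 50

    def test_analytic_ideal_undefined_at_beta_zero(self, potts4, rng):
        configs = [np.zeros((4, 4), dtype=int)] * 4
        with pytest.raises(ValueError, match="undefined"):
            analytic_ideal_decide(configs, potts4, 0.0, rng)
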