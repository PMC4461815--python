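"""Chromatic Gibbs sampler against the exact Boltzmann enumeration."""

import math

import numpy as np
import pytest

from ordertex.sampler import (
    SamplingRequest,
    _check_coloring,
    chi2_gof,
    color_classes,
    conditional_distribution,
    encode_configs,
    enumerate_boltzmann,
    gibbs_sweep,
    make_distractor,
    sample_texture,
    sample_texture_ensemble,
)
from ordertex.texture_model import TextureSetSpec, builtin_specs, energy_batch

from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from conftest import nn_spec

FERRO = -np.eye(3)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    lat=hnp.arrays(np.int64, (4, 4), elements=st.integers(0, 2)),
    pot=hnp.arrays(np.float64, (3, 3), elements=st.floats(-3, 3, allow_nan=False)),
    beta=st.floats(0.0, 2.0),
    p=st.integers(0, 3),
    q=st.integers(0, 3),
)
def test_conditional_is_a_distribution_property(lat, pot, beta, p, q):
    """Conditionals are non-negative, sum to one, and are uniform iff the
    per-state neighbourhood energies coincide."""
    spec = nn_spec((pot, pot.T.copy()))
    probs = conditional_distribution((p, q), lat, spec, beta)
    assert probs.min() >= 0
    assert probs.sum() == pytest.approx(1.0)
    if beta == 0.0:
        np.testing.assert_allclose(probs, 1 / 3)


class TestConditionalDistribution:
    def test_beta_zero_is_uniform(self, potts4, rng):
        lat = rng.integers(0, 3, size=(4, 4))
        p = conditional_distribution((2, 1), lat, potts4, 0.0)
        np.testing.assert_allclose(p, [1 / 3] * 3)

    def test_ferromagnetic_neighbourhood_hand_value(self, potts4):
        # all 4 partners in state 0 at beta=1: P(0) = e^4 / (e^4 + 2)
        lat = np.zeros((4, 4), dtype=int)
        p = conditional_distribution((1, 1), lat, potts4, 1.0)
        e4 = math.exp(4)
        np.testing.assert_allclose(p, [e4 / (e4 + 2), 1 / (e4 + 2), 1 / (e4 + 2)])
        assert p.sum() == pytest.approx(1.0)

    def test_state_relabeling_permutes_output(self, rng):
        U = np.asarray(rng.normal(size=(3, 3)))
        spec = nn_spec((U, U.copy()))
        lat = rng.integers(0, 3, size=(4, 4))
        p = conditional_distribution((0, 0), lat, spec, 0.7)
        perm = np.array([1, 2, 0])
        inv = np.argsort(perm)
        spec2 = nn_spec(tuple(V[np.ix_(inv, inv)] for V in spec.potentials))
        p2 = conditional_distribution((0, 0), perm[lat], spec2, 0.7)
        np.testing.assert_allclose(p2, p[inv], atol=1e-12)

    def test_out_of_range_site(self, potts4):
        with pytest.raises(ValueError, match="out of range"):
            conditional_distribution((4, 0), np.zeros((4, 4), dtype=int), potts4, 1.0)


class TestColorClasses:
    def test_near_neighbour_offsets_give_parity_groups(self):
        spec = TextureSetSpec(
            name="diag", n_states=3,
            offsets=((0, 1), (1, 0), (1, 1), (1, -1)),
            potentials=(FERRO,) * 4,
            lattice_shape=(8, 8),
        )
        groups = color_classes(spec)
        assert len(groups) == 4
        assert _check_coloring(groups, spec)

    def test_even_offset_breaks_parity_but_coloring_stays_valid(self):
        spec = TextureSetSpec(
            name="far", n_states=3,
            offsets=((0, 1), (0, 2)),
            potentials=(FERRO, FERRO),
            lattice_shape=(8, 8),
        )
        groups = color_classes(spec)
        assert _check_coloring(groups, spec)

    def test_odd_lattice_wrap_handled(self):
        # on a 3x3 torus the parity scheme fails at the wrap; a valid
        # colouring must still come back
        spec = nn_spec((FERRO, FERRO), shape=(3, 3))
        groups = color_classes(spec)
        assert _check_coloring(groups, spec)
        total = sum(int(m.sum()) for m in groups)
        assert total == 9

    def test_every_site_in_exactly_one_group(self, potts):
        groups = color_classes(potts)
        stacked = np.sum([m.astype(int) for m in groups], axis=0)
        np.testing.assert_array_equal(stacked, np.ones(potts.lattice_shape, dtype=int))


class TestSweepAndSampling:
    def test_sweep_deterministic_given_seed(self, potts4):
        lat = np.zeros((4, 4), dtype=int)
        a = gibbs_sweep(lat, potts4, 0.8, np.random.default_rng(5))
        b = gibbs_sweep(lat, potts4, 0.8, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_sweep_preserves_shape_and_range(self, potts4, rng):
        out = gibbs_sweep(rng.integers(0, 3, size=(4, 4)), potts4, 2.0, rng)
        assert out.shape == (4, 4)
        assert out.min() >= 0 and out.max() < 3

    def test_sample_texture_reproducible(self, potts4):
        req = SamplingRequest(spec=potts4, beta=0.5, n_sweeps=20, burn_in=10, thin=5, seed=11)
        a = sample_texture(req)
        b = sample_texture(req)
        assert len(a) == 4
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_beta_zero_state_frequencies_uniform(self, potts):
        samples = sample_texture_ensemble(potts, 0.0, 100, seed=2, n_chains=50, burn_in=20, thin=1)
        counts = np.bincount(samples.ravel(), minlength=3)
        n = samples.size
        se = math.sqrt(n * (1 / 3) * (2 / 3))
        assert np.all(np.abs(counts - n / 3) < 3 * se)

    def test_invalid_request_rejected(self, potts4):
        with pytest.raises(ValueError):
            SamplingRequest(spec=potts4, beta=-1.0, n_sweeps=10)
        with pytest.raises(ValueError):
            SamplingRequest(spec=potts4, beta=1.0, n_sweeps=10, thin=0)


class TestEnumerationOracle:
    def test_two_by_two_beta_zero_uniform(self):
        spec = nn_spec((FERRO, FERRO), shape=(2, 2))
        probs = enumerate_boltzmann(spec, 0.0)
        assert len(probs) == 81
        np.testing.assert_allclose(probs, 1 / 81)

    def test_probabilities_translation_invariant(self):
        spec = nn_spec((FERRO, FERRO), shape=(2, 3))
        probs = enumerate_boltzmann(spec, 0.7)
        assert probs.sum() == pytest.approx(1.0)
        codes = np.arange(len(probs))
        digits = np.array([(codes // 3**k) % 3 for k in range(5, -1, -1)]).T
        lattices = digits.reshape(-1, 2, 3)
        rolled = np.roll(lattices, shift=(0, 1), axis=(1, 2))
        np.testing.assert_allclose(probs[encode_configs(rolled, 3)], probs, rtol=1e-12)

    def test_lattice_too_large_refused(self, potts):
        with pytest.raises(ValueError, match="too large"):
            enumerate_boltzmann(potts, 0.5)

    def test_gibbs_mean_energy_matches_exact(self):
        spec = nn_spec((FERRO, FERRO), shape=(3, 3))
        beta = 0.5
        probs = enumerate_boltzmann(spec, beta)
        codes = np.arange(len(probs))
        digits = np.array([(codes // 3**k) % 3 for k in range(8, -1, -1)]).T
        exact_mean = float(probs @ energy_batch(digits.reshape(-1, 3, 3), spec))
        samples = sample_texture_ensemble(spec, beta, 20000, seed=4, n_chains=200, burn_in=300, thin=2)
        e = energy_batch(samples, spec)
        assert abs(e.mean() - exact_mean) < 4 * e.std() / math.sqrt(len(e) / 10)

    def test_gibbs_samples_fit_exact_distribution(self):
        spec = nn_spec((FERRO, FERRO), shape=(2, 2))
        beta = 0.6
        probs = enumerate_boltzmann(spec, beta)
        samples = sample_texture_ensemble(spec, beta, 50000, seed=9, n_chains=100, burn_in=200, thin=2)
        observed = np.bincount(encode_configs(samples, 3), minlength=81)
        chi2, dof, p = chi2_gof(observed, probs)
        assert p > 1e-3


class TestDistractors:
    def test_permuted_preserves_marginal_counts(self, potts, rng):
        target = rng.integers(0, 3, size=(32, 32))
        d = make_distractor(potts, "permuted", rng, target=target)
        np.testing.assert_array_equal(np.sort(d.ravel()), np.sort(target.ravel()))

    def test_permuted_reproducible(self, potts, rng):
        target = rng.integers(0, 3, size=(32, 32))
        a = make_distractor(potts, "permuted", np.random.default_rng(3), target=target)
        b = make_distractor(potts, "permuted", np.random.default_rng(3), target=target)
        np.testing.assert_array_equal(a, b)

    def test_uniform_counts_within_three_se(self, potts):
        rng = np.random.default_rng(12)
        counts = np.zeros(3)
        n_draws = 30
        for _ in range(n_draws):
            counts += np.bincount(make_distractor(potts, "uniform", rng).ravel(), minlength=3)
        n = 1024 * n_draws
        se = math.sqrt(n * (1 / 3) * (2 / 3))
        assert np.all(np.abs(counts - n / 3) < 3 * se)

    def test_permuted_requires_target(self, potts, rng):
        with pytest.raises(ValueError, match="target"):
            make_distractor(potts, "permuted", rng)


def test_mean_energy_non_increasing_in_beta():
    """Stronger coupling concentrates mass on low-energy configurations."""
    betas = [0.0, 0.4, 1.2]
    for spec in builtin_specs():
        small = spec.with_shape((16, 16))
        means = []
        for beta in betas:
            s = sample_texture_ensemble(small, beta, 200, seed=21, n_chains=100, burn_in=400, thin=2)
            means.append(energy_batch(s, small).mean())
        assert means[0] > means[1] > means[2]
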