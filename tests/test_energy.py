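"""Energy matrices, the random generator, occupancy and landscape enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bindsim import (
    EnergyMatrix,
    GeneratorConfig,
    InvalidConfigError,
    all_sequences,
    enumerate_landscape,
    indices_to_seq,
    mutate_probability,
    occupancy,
    random_energy_matrix,
    sequence_energy,
)


class TestGenerator:
    def test_structure_and_gauge(self):
        rng = np.random.default_rng(0)
        model = random_energy_matrix(GeneratorConfig(m=8), rng)
        assert model.m == 8
        # exactly one zero per column, all others strictly positive
        assert np.all(model.eps.min(axis=0) == 0)
        assert np.all((model.eps == 0).sum(axis=0) == 1)
        assert np.all(model.eps[model.eps != 0] > 0)
        assert model.offset == 0.0

    def test_reproducible_under_seed(self):
        a = random_energy_matrix(GeneratorConfig(m=8, seed=7))
        b = random_energy_matrix(GeneratorConfig(m=8, seed=7))
        assert np.array_equal(a.eps, b.eps)

    def test_zero_variance_gives_constant_energies(self):
        model = random_energy_matrix(GeneratorConfig(m=3, energy_sd=0.0, seed=1))
        nonzero = model.eps[model.eps != 0]
        assert nonzero.shape == (9,)
        assert np.all(nonzero == 2.5)

    def test_truncated_normal_mean(self):
        """Sample mean of non-preferred energies matches the closed-form
        mean of the positive-truncated N(2.5, 1)."""
        rng = np.random.default_rng(123)
        draws = []
        cfg = GeneratorConfig(m=10)
        for _ in range(42):  # 42 * 30 = 1260 columns -> 3780 draws... keep 10k scale
            model = random_energy_matrix(cfg, rng)
            draws.append(model.eps[model.eps != 0])
        draws = np.concatenate(draws)
        assert draws.size >= 1000
        expected = stats.truncnorm.mean(a=(0 - 2.5) / 1.0, b=np.inf, loc=2.5, scale=1.0)
        assert np.isclose(draws.mean(), expected, atol=3 * 1.0 / np.sqrt(draws.size))

    @pytest.mark.parametrize("m,sd", [(0, 1.0), (-2, 1.0), (3, -0.1)])
    def test_invalid_config(self, m, sd):
        with pytest.raises(InvalidConfigError):
            GeneratorConfig(m=m, energy_sd=sd)


class TestSequenceEnergy:
    def test_preferred_sequence_scores_offset(self, model_m8):
        assert sequence_energy(model_m8, model_m8.preferred_sequence()) == pytest.approx(
            model_m8.offset
        )

    def test_hand_sum_toy(self, toy_m2):
        assert sequence_energy(toy_m2, "CG") == pytest.approx(2.2)
        assert sequence_energy(toy_m2, "AA") == pytest.approx(0.0)

    def test_additivity_of_substitutions(self, model_m8):
        rng = np.random.default_rng(5)
        seq = rng.integers(0, 4, 8)
        for j in range(8):
            for b in range(4):
                new = seq.copy()
                new[j] = b
                delta = sequence_energy(model_m8, new) - sequence_energy(model_m8, seq)
                assert delta == pytest.approx(model_m8.eps[b, j] - model_m8.eps[seq[j], j])

    def test_length_mismatch_and_bad_base(self, model_m8):
        with pytest.raises(ValueError):
            sequence_energy(model_m8, "ACGT")
        with pytest.raises(ValueError):
            sequence_energy(model_m8, "ACGTACGN")

    def test_zero_gauge_enforced(self):
        eps = np.ones((4, 3))
        with pytest.raises(ValueError):
            EnergyMatrix(eps)
        model = EnergyMatrix.from_array(eps, regauge=True)
        assert np.all(model.eps == 0)
        assert model.offset == pytest.approx(3.0)


class TestOccupancy:
    @pytest.mark.parametrize(
        "E,mu,expected",
        [(0.0, 3.0, 0.95), (0.0, 0.0, 0.50), (0.0, -3.0, 0.05)],
    )
    def test_reference_occupancies_round_to_two_decimals(self, E, mu, expected):
        assert round(occupancy(E, mu), 2) == expected

    def test_symmetry_point_and_low_concentration(self):
        assert occupancy(2.7, 2.7) == pytest.approx(0.5)
        assert occupancy(0.0, -3.0) == pytest.approx(1 / (1 + np.exp(3)))

    def test_monotonicity(self):
        E = np.linspace(-5, 5, 101)
        p = occupancy(E, 1.3)
        assert np.all(np.diff(p) < 0)
        assert np.all((p > 0) & (p < 1))
        mus = np.linspace(-5, 5, 101)
        assert np.all(np.diff([occupancy(0.7, mu) for mu in mus]) > 0)


class TestMutateProbability:
    def test_identity_at_zero_cost(self):
        assert mutate_probability(0.37, 0.0, mu=1.0) == pytest.approx(0.37)

    def test_mutation_from_reported_probability(self):
        # 0.62 -> 0.23 under a +1.69 kT mutation
        assert round(float(mutate_probability(0.62, 1.69, mu=3.0)), 2) == 0.23

    def test_mutation_from_preferred_site(self):
        # the preferred site at mu=3 (occupancy 0.9526, displayed 0.95)
        # drops to 0.79 under a +1.69 kT mutation
        p0 = occupancy(0.0, 3.0)
        assert round(float(mutate_probability(p0, 1.69, mu=3.0)), 2) == 0.79

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_degenerate_probability(self, p):
        with pytest.raises(ValueError):
            mutate_probability(p, 1.0)

    @given(
        p=st.floats(1e-6, 1 - 1e-6),
        dE=st.floats(-15, 15),
        mu1=st.floats(-25, 25),
        mu2=st.floats(-25, 25),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_mu_invariance(self, p, dE, mu1, mu2):
        """The chemical potential cancels: results agree to >= 10 significant digits."""
        a = float(mutate_probability(p, dE, mu1))
        b = float(mutate_probability(p, dE, mu2))
        assert a == pytest.approx(b, rel=1e-10)


class TestLandscape:
    def test_counts_and_canonical_order(self, model_m8):
        ls = enumerate_landscape(model_m8, 0.0)
        assert ls.n == 4**8
        strings = [indices_to_seq(ls.seqs[i]) for i in (0, 1, 4, ls.n - 1)]
        assert strings == ["AAAAAAAA", "AAAAAAAC", "AAAAAACA", "TTTTTTTT"]

    def test_m1_occupancies(self):
        model = EnergyMatrix(np.array([[0.0], [1.0], [2.0], [3.0]]))
        ls = enumerate_landscape(model, 0.0)
        expected = [1 / (1 + np.exp(E)) for E in (0, 1, 2, 3)]
        np.testing.assert_allclose(ls.occupancies, expected)

    def test_matches_nested_loop_oracle(self, model_m3):
        """Exact agreement with a naive per-sequence loop for m=3."""
        mu = 0.8
        ls = enumerate_landscape(model_m3, mu)
        i = 0
        for b1, b2, b3 in itertools.product(range(4), repeat=3):
            E = model_m3.eps[b1, 0] + model_m3.eps[b2, 1] + model_m3.eps[b3, 2]
            assert tuple(ls.seqs[i]) == (b1, b2, b3)
            assert ls.energies[i] == pytest.approx(E, abs=1e-12)
            assert ls.occupancies[i] == pytest.approx(1 / (1 + np.exp(E - mu)), abs=1e-12)
            i += 1
        # expected number of bound sites matches brute-force summation
        brute = sum(
            1 / (1 + np.exp(model_m3.eps[a, 0] + model_m3.eps[b, 1] + model_m3.eps[c, 2] - mu))
            for a, b, c in itertools.product(range(4), repeat=3)
        )
        assert ls.occupancies.sum() == pytest.approx(brute, rel=1e-12)

    def test_internal_consistency_of_occupancy_forms(self, model_m3):
        """K e^mu / (K e^mu + 1) equals 1/(1+e^(E-mu)) for every record."""
        ls = enumerate_landscape(model_m3, -1.7)
        K = ls.affinities
        alt = K * np.exp(ls.mu) / (K * np.exp(ls.mu) + 1)
        np.testing.assert_allclose(ls.occupancies, alt, rtol=1e-12)

    def test_rank_order_invariant_to_mu(self, model_m3):
        ls = enumerate_landscape(model_m3, 0.0)
        base_order = np.argsort(-ls.occupancies, kind="stable")
        for mu in (-6.0, -1.0, 2.0, 8.0):
            order = np.argsort(-ls.with_mu(mu).occupancies, kind="stable")
            np.testing.assert_array_equal(order, base_order)
        np.testing.assert_array_equal(base_order, np.argsort(ls.energies, kind="stable"))

    def test_enumeration_guard(self):
        with pytest.raises(ValueError, match="guard"):
            all_sequences(13)
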