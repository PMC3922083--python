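"""Exact enumeration, Gibbs sampling, free energy, CD-k and discretization."""

import numpy as np
import pytest

from spikecd.boltzmann import (RBMParams, all_states, cd_k_update, discretize,
                               energy, exact_distribution, free_energy,
                               gibbs_sample, random_rbm)
from spikecd.decoding import kl_divergence


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestEnergy:
    def test_zero_state_zero_energy(self, rbm_2x2):
        assert energy(np.zeros(4), rbm_2x2) == 0.0

    def test_no_coupling_reduces_to_bias_terms(self):
        rbm = RBMParams(W=np.zeros((2, 2)), b_v=[0.5, -1.0], b_h=[2.0, 0.0])
        assert energy([1, 1, 1, 0], rbm) == pytest.approx(-(0.5 - 1.0 + 2.0))

    def test_hand_evaluated_pair(self):
        rbm = RBMParams(W=[[1.0]], b_v=[0.0], b_h=[0.0])
        assert energy([1, 1], rbm) == -1.0

    def test_rejects_non_binary(self, rbm_2x2):
        with pytest.raises(ValueError):
            energy([0.5, 0, 1, 0], rbm_2x2)


class TestExactDistribution:
    def test_uniform_when_unparameterized(self):
        rbm = RBMParams(W=[[0.0]], b_v=[0.0], b_h=[0.0])
        np.testing.assert_allclose(exact_distribution(rbm).p, 0.25)

    def test_single_unit_logistic(self):
        for b in (-1.0, 0.3, 2.0):
            rbm = RBMParams(W=[[0.0]], b_v=[b], b_h=[-50.0])
            marg = exact_distribution(rbm).marginal([0])
            assert marg.p[1] == pytest.approx(_sigmoid(b), rel=1e-6)

    def test_normalization_and_positivity(self, rbm_5x5):
        d = exact_distribution(rbm_5x5)
        assert d.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(d.p >= 0)

    def test_enumeration_guard(self):
        big = RBMParams(W=np.zeros((15, 15)), b_v=np.zeros(15),
                        b_h=np.zeros(15))
        with pytest.raises(ValueError):
            exact_distribution(big)


class TestGibbs:
    def test_independent_marginals_without_coupling(self):
        rbm = RBMParams(W=np.zeros((2, 3)), b_v=[0.0, 1.0],
                        b_h=[-1.0, 0.0, 0.5])
        V, H = gibbs_sample(rbm, 20000, rng_seed=0)
        np.testing.assert_allclose(H.mean(axis=0), _sigmoid(rbm.b_h),
                                   atol=0.02)
        np.testing.assert_allclose(V.mean(axis=0), _sigmoid(rbm.b_v),
                                   atol=0.02)

    def test_kl_to_exact_decreases_with_chain_length(self, rbm_5x5):
        """The empirical joint converges toward the enumerated law."""
        exact = exact_distribution(rbm_5x5)
        V, H = gibbs_sample(rbm_5x5, 100000, rng_seed=1)
        S = np.hstack([V, H]).astype(np.int64)
        codes = S @ (1 << np.arange(10))
        kls = []
        for n in (1000, 10000, 100000):
            counts = np.bincount(codes[:n], minlength=1024) + 1.0
            kls.append(kl_divergence(counts / counts.sum(), exact))
        assert kls[0] > kls[1] > kls[2]

    def test_seed_reproducibility(self, rbm_5x5):
        a = gibbs_sample(rbm_5x5, 100, rng_seed=3)
        b = gibbs_sample(rbm_5x5, 100, rng_seed=3)
        np.testing.assert_array_equal(a[0], b[0])

    def test_against_sklearn_gibbs_marginals(self):
        """Independent cross-check: sklearn's BernoulliRBM implements the
        same block-Gibbs conditionals; a chain driven by its gibbs() method
        must land on the same visible marginals as ours."""
        from sklearn.neural_network import BernoulliRBM
        rng = np.random.default_rng(7)
        rbm = RBMParams(W=rng.normal(0, 0.8, (3, 2)),
                        b_v=rng.normal(0, 0.5, 3), b_h=rng.normal(0, 0.5, 2))
        sk = BernoulliRBM(n_components=2)
        sk.components_ = rbm.W.T
        sk.intercept_visible_ = rbm.b_v
        sk.intercept_hidden_ = rbm.b_h
        sk.random_state = None
        rs = np.random.RandomState(0)
        sk.random_state_ = rs
        v = np.zeros((200, 3))
        ours_V, _ = gibbs_sample(rbm, 4000, rng_seed=2)
        sk_means = []
        for _ in range(40):
            v = sk.gibbs(v)
            sk_means.append(v.mean(axis=0))
        np.testing.assert_allclose(ours_V[200:].mean(axis=0),
                                   np.mean(sk_means[5:], axis=0), atol=0.04)


class TestFreeEnergy:
    def test_uniform_hidden_layer(self):
        rbm = RBMParams(W=np.zeros((2, 3)), b_v=np.zeros(2), b_h=np.zeros(3))
        assert free_energy([0, 1], rbm) == pytest.approx(-3 * np.log(2))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_marginalization(self, seed):
        rng = np.random.default_rng(seed)
        n_v, n_h = 3, rng.integers(1, 9)
        rbm = RBMParams(W=rng.normal(0, 1.2, (n_v, n_h)),
                        b_v=rng.normal(0, 1, n_v), b_h=rng.normal(0, 1, n_h))
        v = (rng.random(n_v) < 0.5).astype(float)
        brute = sum(np.exp(-energy(np.concatenate([v, h]), rbm))
                    for h in all_states(n_h))
        assert free_energy(v, rbm) == pytest.approx(-np.log(brute), abs=1e-10)

    def test_bias_shift_linearity(self, rbm_2x2):
        v = np.array([1.0, 0.0])
        c = 0.7
        shifted = RBMParams(W=rbm_2x2.W, b_v=rbm_2x2.b_v + c,
                            b_h=rbm_2x2.b_h)
        assert free_energy(v, shifted) == pytest.approx(
            free_energy(v, rbm_2x2) - c * v.sum())


class TestCDk:
    def test_zero_learning_rate_is_identity(self, rbm_2x2):
        out = cd_k_update(rbm_2x2, [[1, 0]], k=1, epsilon=0.0, rng_seed=0)
        np.testing.assert_array_equal(out.W, rbm_2x2.W)

    def test_mean_update_matches_conditional_enumeration(self):
        """1+1 machine, clamped v=1: the expected weight step is
        eps * (p_d - E[v_r p_r]) with p_d = logistic(b_h + w), averaged over
        the stochastic reconstruction chain (enumerated exactly)."""
        w, bv, bh, eps = 0.7, -0.3, 0.2, 0.5
        rbm = RBMParams(W=[[w]], b_v=[bv], b_h=[bh])
        p_d = _sigmoid(bh + w)
        # enumerate the CD-1 chain: h0 ~ Bern(p_d); v1 | h0; h1 | v1
        e_vp = 0.0
        for h0 in (0, 1):
            ph0 = p_d if h0 else 1 - p_d
            for v1 in (0, 1):
                pv1 = _sigmoid(bv + w * h0)
                pv1 = pv1 if v1 else 1 - pv1
                e_vp += ph0 * pv1 * v1 * _sigmoid(bh + w * v1)
        expected = eps * (1.0 * p_d - e_vp)
        steps = [cd_k_update(rbm, [[1]], k=1, epsilon=eps,
                             rng_seed=s).W[0, 0] - w for s in range(4000)]
        se = np.std(steps) / np.sqrt(len(steps))
        assert np.mean(steps) == pytest.approx(expected, abs=4 * se)

    def test_training_tightens_model_to_data(self):
        """2000 CD updates on a two-pattern dataset reduce the KL from the
        data law to the visible marginal, versus initialization."""
        rng = np.random.default_rng(0)
        rbm = RBMParams(W=rng.normal(0, 0.1, (5, 5)), b_v=np.zeros(5),
                        b_h=np.zeros(5))
        data = np.array([[1, 1, 1, 0, 0], [0, 0, 1, 1, 1]], dtype=float)
        p_data = np.zeros(32)
        for row in data:
            p_data[int(row @ (1 << np.arange(5)))] = 0.5

        def kl_to_model(r):
            marg = exact_distribution(r).marginal(range(5))
            return kl_divergence(p_data, marg.p)

        before = kl_to_model(rbm)
        for s in range(2000):
            rbm = cd_k_update(rbm, data, k=1, epsilon=0.05, rng_seed=s)
        assert kl_to_model(rbm) < before


class TestDiscretize:
    def test_level_grid_arithmetic(self):
        """mu=0, sd=1 group, 5 bits: 32 levels spanning (-4.5, 4.5) with
        spacing 9/31."""
        x = np.array([-1.0, 1.0])    # mean 0, population std 1
        rbm = RBMParams(W=x.reshape(2, 1) @ [[1.0]],
                        b_v=np.zeros(2), b_h=np.zeros(1))
        out = discretize(rbm, 5, stats=((0.0, 1.0), (0.0, 1.0), (0.0, 1.0)))
        levels = np.linspace(-4.5, 4.5, 32)
        spacing = 9.0 / 31.0
        assert spacing == pytest.approx(0.2903, abs=1e-4)
        for v in out.W.ravel():
            assert np.min(np.abs(levels - v)) < 1e-12

    def test_refinement_limit(self, rbm_5x5):
        out = discretize(rbm_5x5, 16)
        sd = rbm_5x5.W.std()
        half_spacing = 0.5 * 9 * sd / (2**16 - 1)
        assert np.max(np.abs(out.W - rbm_5x5.W)) <= half_spacing + 1e-12

    def test_projection_is_idempotent(self, rbm_5x5):
        stats = tuple((float(x.mean()), float(x.std()))
                      for x in (rbm_5x5.W, rbm_5x5.b_v, rbm_5x5.b_h))
        once = discretize(rbm_5x5, 5, stats=stats)
        twice = discretize(once, 5, stats=stats)
        np.testing.assert_array_equal(once.W, twice.W)
        np.testing.assert_array_equal(once.b_v, twice.b_v)

    def test_constant_group_unchanged(self):
        rbm = RBMParams(W=np.full((2, 2), 0.3), b_v=np.zeros(2),
                        b_h=np.zeros(2))
        out = discretize(rbm, 3)
        np.testing.assert_array_equal(out.W, rbm.W)
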