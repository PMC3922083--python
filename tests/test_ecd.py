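"""Gating signal, STDP traces, the CD-equivalence and spiking training."""

import numpy as np
import pytest

from spikecd.boltzmann import RBMParams, exact_distribution
from spikecd.decoding import kl_divergence
from spikecd.ecd import (effective_eta, gating, stdp_on_spike, train,
                         update_traces)
from spikecd.params import GatingSchedule, NeuronParams, STDPConfig


@pytest.fixture()
def sched():
    return GatingSchedule(T=50e-3, tau_br=10e-3)


@pytest.fixture()
def cfg():
    return STDPConfig(A=1.0, tau_stdp=4e-3)


class TestGating:
    def test_branch_values(self, sched):
        assert gating(0.0, sched) == 0
        assert gating(0.030, sched) == 1
        assert gating(0.070, sched) == -1
        assert gating(0.055, sched) == 0     # reconstruction burn-in

    def test_zero_mean_over_epoch(self, sched):
        t = np.linspace(0, 0.1, 100001)[:-1]
        g = gating(t, sched)
        assert abs(np.trapezoid(g, t)) < 1e-4

    def test_no_updates_inside_burn_in(self, sched):
        for t in (0.001, 0.009, 0.0505, 0.059):
            assert gating(t, sched) == 0

    def test_periodicity(self, sched):
        assert gating(0.030, sched) == gating(0.130, sched) == 1


class TestTraces:
    def test_silent_decay_is_geometric(self, cfg):
        tr = np.array([1.0, 2.0])
        out = update_traces(tr, [], 1e-3, cfg)
        np.testing.assert_allclose(out, tr * np.exp(-0.25))

    def test_single_spike_closed_form(self, cfg):
        """A=1 trace read 2 ms after the spike equals e^-0.5."""
        tr = np.zeros(1)
        tr = update_traces(tr, [0], 0.0, cfg)
        for _ in range(20):
            tr = update_traces(tr, [], 1e-4, cfg)
        assert tr[0] == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_superposition(self, cfg):
        a = update_traces(np.zeros(1), [0], 0.0, cfg)
        a = update_traces(a, [0], 1e-3, cfg)
        expect = cfg.A * (np.exp(-1e-3 / cfg.tau_stdp) + 1.0)
        assert a[0] == pytest.approx(expect, rel=1e-12)

    def test_recursion_equals_integral_definition(self, cfg):
        """The per-step recursion reproduces A sum_k exp(-(t-t_k)/tau) for an
        arbitrary spike list, to near machine precision."""
        rng = np.random.default_rng(0)
        spike_steps = np.unique(rng.integers(0, 400, 25))
        dt = 1e-4
        tr = np.zeros(1)
        for k in range(401):
            tr = update_traces(tr, [0] if k in spike_steps else [], dt, cfg)
            if k == 400:
                break
        t = 400 * dt
        expect = cfg.A * np.sum(np.exp(-(t - spike_steps * dt) / cfg.tau_stdp))
        # decay of the initial jump at the spike step itself: spikes are added
        # after the decay of their own step, so t_k = step * dt exactly
        assert tr[0] == pytest.approx(expect, rel=1e-10)


class TestSTDPOnSpike:
    def test_gate_zero_is_identity(self):
        W = np.ones((2, 3))
        out = stdp_on_spike(W, "visible", 0, np.array([1.0, 2.0, 3.0]), 0)
        np.testing.assert_array_equal(out, W)

    def test_two_event_pair_sum(self, cfg):
        """Visible spike then hidden spike 2 ms later: with causal
        eligibility traces the pair is committed once, with weight
        A K(delta) = e^-0.5 — the per-pair weight that makes the learning
        rate come out as eta = 2 A duty tau_stdp."""
        dt, n_steps = 1e-4, 20
        W = np.zeros((1, 1))
        tv = np.zeros(1)
        th = np.zeros(1)
        # visible spike at t=0: hidden trace is empty, no weight change
        W = stdp_on_spike(W, "visible", 0, th, 1)
        tv = update_traces(tv, [0], 0.0, cfg)
        for _ in range(n_steps):
            tv = update_traces(tv, [], dt, cfg)
            th = update_traces(th, [], dt, cfg)
        # hidden spike at t=2ms reads the visible trace
        W = stdp_on_spike(W, "hidden", 0, tv, 1)
        th = update_traces(th, [0], 0.0, cfg)
        assert W[0, 0] == pytest.approx(np.exp(-0.5), rel=1e-9)

    def test_order_invariance(self, cfg):
        """Swapping which layer fires first leaves the pair update unchanged
        (symmetric window)."""
        def pair(first):
            dt, lag = 1e-4, 30
            W = np.zeros((1, 1))
            tv, th = np.zeros(1), np.zeros(1)
            a, b = (("visible", "hidden") if first == "v"
                    else ("hidden", "visible"))
            W = stdp_on_spike(W, a, 0, th if a == "visible" else tv, 1)
            if a == "visible":
                tv = update_traces(tv, [0], 0.0, cfg)
            else:
                th = update_traces(th, [0], 0.0, cfg)
            for _ in range(lag):
                tv = update_traces(tv, [], dt, cfg)
                th = update_traces(th, [], dt, cfg)
            W = stdp_on_spike(W, b, 0, tv if b == "hidden" else th, 1)
            return W[0, 0]

        assert pair("v") == pytest.approx(pair("h"), rel=1e-12)


class TestEffectiveEta:
    def test_reference_configuration(self, sched):
        """2T=100 ms, tau_br=10 ms, tau_stdp=4 ms and A=10 give eta=3.2e-2."""
        assert effective_eta(STDPConfig(A=10.0, tau_stdp=4e-3),
                             sched) == pytest.approx(3.2e-2, rel=1e-12)

    def test_vanishes_as_burn_in_fills_phase(self):
        sched = GatingSchedule(T=50e-3, tau_br=49.999e-3)
        assert effective_eta(STDPConfig(A=1.0, tau_stdp=4e-3), sched) < 1e-5

    def test_linear_in_A(self, sched, cfg):
        one = effective_eta(cfg, sched)
        two = effective_eta(STDPConfig(A=2 * cfg.A, tau_stdp=cfg.tau_stdp),
                            sched)
        assert two == pytest.approx(2 * one)


class TestCDEquivalence:
    def test_epoch_average_matches_rate_product_formula(self, sched, cfg):
        """Frozen independent Poisson activity: the epoch-averaged gated-STDP
        update equals eta (v+ h+ - v- h-) within 3 SE of 100 repetitions."""
        rng = np.random.default_rng(42)
        dt = 2e-5
        rates = {"v+": 100.0, "h+": 80.0, "v-": 40.0, "h-": 30.0}
        eta = effective_eta(cfg, sched)
        target = eta * (rates["v+"] * rates["h+"] - rates["v-"] * rates["h-"])
        steps = int(round(2 * sched.T / dt))
        deltas = []
        for _ in range(100):
            W = np.zeros((1, 1))
            tv, th = np.zeros(1), np.zeros(1)
            for k in range(steps):
                t = k * dt
                g = gating(t, sched)
                phase = "+" if t < sched.T else "-"
                sv = rng.random() < rates["v" + phase] * dt
                sh = rng.random() < rates["h" + phase] * dt
                tv = update_traces(tv, [], dt, cfg)
                th = update_traces(th, [], dt, cfg)
                if sv:
                    W = stdp_on_spike(W, "visible", 0, th, g)
                    tv = update_traces(tv, [0], 0.0, cfg)
                if sh:
                    W = stdp_on_spike(W, "hidden", 0, tv, g)
                    th = update_traces(th, [0], 0.0, cfg)
            deltas.append(W[0, 0] / (2 * sched.T))
        se = np.std(deltas) / np.sqrt(len(deltas))
        assert np.mean(deltas) == pytest.approx(target, abs=3 * se)


class TestTrain:
    def _setup(self, fit, n_epochs, A):
        rng = np.random.default_rng(0)
        rbm0 = RBMParams(W=rng.normal(0, 0.1, (6, 4)), b_v=np.zeros(6),
                         b_h=np.zeros(4))
        from spikecd.calibration import inverse_transfer
        pats = np.array([[1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1]], float)
        probs = np.where(pats > 0.5, 0.98, 1e-5)
        currents = inverse_transfer(probs, fit)
        order = rng.integers(0, 2, n_epochs)
        sched = GatingSchedule(T=50e-3, tau_br=10e-3, n_epochs=n_epochs)
        return rbm0, currents, order, sched, STDPConfig(A=A, tau_stdp=4e-3)

    def test_zero_magnitude_leaves_parameters_unchanged(self, fit, neuron):
        rbm0, currents, order, sched, _ = self._setup(fit, 5, 1.0)
        cfg = STDPConfig(A=0.0, tau_stdp=4e-3)
        out, _ = train(rbm0, fit, currents, order, sched, cfg, neuron,
                       rng_seed=1)
        np.testing.assert_array_equal(out.W, rbm0.W)
        np.testing.assert_array_equal(out.b_v, rbm0.b_v)

    def test_learning_improves_model_of_patterns(self, fit, neuron):
        """500 epochs on two orthogonal patterns pull the exact visible
        marginal toward the two-pattern law."""
        rbm0, currents, order, sched, cfg = self._setup(fit, 500, 0.05)
        p_data = np.zeros(64)
        p_data[0b000111] = 0.5
        p_data[0b111000] = 0.5

        def score(rbm):
            marg = exact_distribution(rbm).marginal(range(6))
            return kl_divergence(p_data, marg.p)

        out, log = train(rbm0, fit, currents, order, sched, cfg, neuron,
                         rng_seed=2)
        assert score(out) < score(rbm0)
        assert log.mean_weight.size == 1000

    def test_symmetric_store_shared_between_directions(self, fit, neuron):
        """The learned parameters come from one shared matrix; training can
        only ever produce one W (checked via the returned object's shape and
        by reproducibility across identical runs)."""
        rbm0, currents, order, sched, cfg = self._setup(fit, 20, 0.05)
        a, _ = train(rbm0, fit, currents, order, sched, cfg, neuron,
                     rng_seed=3)
        b, _ = train(rbm0, fit, currents, order, sched, cfg, neuron,
                     rng_seed=3)
        np.testing.assert_array_equal(a.W, b.W)
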