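"""scikit-learn style estimators wrapping the spiking RBM machinery.

``EventDrivenRBM`` trains a spiking restricted Boltzmann machine with the
event-driven (STDP-gated) contrastive-divergence rule; ``CDRBMClassifier``
is the conventional CD-k / block-Gibbs baseline on the same supervised
architecture; ``TransferCurveCalibration`` fits the sigmoid transfer curve
of a noisy integrate-and-fire neuron from (current, rate) measurements.
All three follow the fit/predict contract, validate their inputs and expose
fitted attributes with trailing underscores, so they compose with sklearn
pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import boltzmann, calibration, ecd, experiments
from .boltzmann import RBMParams
from .calibration import TransferFit
from .dynamics import simulate
from .params import GatingSchedule, NeuronParams, STDPConfig

__all__ = [
    "TransferCurveCalibration",
    "CDRBMClassifier",
    "EventDrivenRBM",
]


class TransferCurveCalibration(BaseEstimator, RegressorMixin):
    """Sigmoid transfer-curve regression for a noisy I&F neuron.

    Fits ``log(rate^-1 - tau_r) = -beta I - log gamma`` from (current, rate)
    pairs.  ``X`` is the injected current in amperes (one column), ``y`` the
    measured firing rate in Hz.

    Parameters
    ----------
    tau_r : float
        Refractory period (s); the inverse saturation rate.
    weighting : {"probability", "none"}
        Probability weighting makes the regression minimize on-probability
        error rather than log-domain error.
    """

    def __init__(self, tau_r: float = 4e-3, weighting: str = "probability"):
        self.tau_r = tau_r
        self.weighting = weighting

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=2)
        if X.shape[1] != 1:
            raise ValueError("X must be a single column of currents (A)")
        fit = calibration.fit_sigmoid(np.column_stack([X[:, 0], y]),
                                      self.tau_r, weighting=self.weighting)
        self.beta_ = fit.beta
        self.gamma_ = fit.gamma
        self.residual_ = fit.fit_residual
        self.transfer_fit_ = fit
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "transfer_fit_")
        X = check_array(X)
        return calibration.transfer_rate(X[:, 0], self.transfer_fit_)

    def inverse(self, p):
        """Clamp currents producing on-probabilities ``p``."""
        check_is_fitted(self, "transfer_fit_")
        return calibration.inverse_transfer(p, self.transfer_fit_)

    @classmethod
    def from_neuron(cls, neuron: NeuronParams | None = None,
                    t_sim: float = 5.0, rng_seed: int = 0,
                    **kwargs) -> "TransferCurveCalibration":
        """Calibrate by simulating a neuron over the default current grid."""
        neuron = neuron or NeuronParams()
        fit, grid = calibration.calibrate(neuron, t_sim=t_sim,
                                          rng_seed=rng_seed, **kwargs)
        est = cls(tau_r=fit.tau_r)
        est.beta_ = fit.beta
        est.gamma_ = fit.gamma
        est.residual_ = fit.fit_residual
        est.transfer_fit_ = fit
        est.grid_ = grid
        est.n_features_in_ = 1
        return est


class _SupervisedRBM(ClassifierMixin, BaseEstimator):
    """Shared plumbing: architecture assembly and free-energy prediction."""

    def _setup(self, X, y):
        X, y = check_X_y(X, y)
        if np.any(X < 0) or np.any(X > 1):
            raise ValueError("pixel values must lie in [0, 1]")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.arch_ = experiments.ArchitectureSpec(
            n_vd=X.shape[1], n_labels=self.classes_.size,
            n_per_class=self.n_per_class, n_h=self.n_hidden)
        self.n_features_in_ = X.shape[1]
        return X, y_idx

    def _joint_visible(self, X, y_idx):
        V = np.zeros((X.shape[0], self.arch_.n_visible))
        V[:, :self.arch_.n_vd] = (np.asarray(X) > 0.5).astype(float)
        for k, ell in enumerate(y_idx):
            V[k, self.arch_.label_slice(int(ell))] = 1.0
        return V

    def predict(self, X):
        check_is_fitted(self, "rbm_")
        X = check_array(X)
        Xb = (X > 0.5).astype(float)
        idx = [experiments.classify_by_free_energy(self.rbm_, self.arch_, v)
               for v in Xb]
        return self.classes_[np.asarray(idx)]

    def predict_proba(self, X):
        check_is_fitted(self, "rbm_")
        X = check_array(X)
        Xb = (X > 0.5).astype(float)
        return np.vstack([
            experiments.exact_label_posterior(self.rbm_, self.arch_, v)
            for v in Xb])


class CDRBMClassifier(_SupervisedRBM):
    """Supervised RBM trained with standard contrastive divergence (CD-k).

    The visible layer is the concatenation of binarized pixels and a
    one-hot class-population code (``n_per_class`` neurons per label).
    Prediction picks the label with the lowest free energy.

    Parameters largely follow the usual CD conventions: ``epsilon`` is the
    learning rate, ``k`` the number of alternating Gibbs steps, and
    ``n_updates`` the number of minibatch updates.
    """

    def __init__(self, n_hidden: int = 8, n_per_class: int = 1, k: int = 1,
                 epsilon: float = 0.1, n_updates: int = 500,
                 batch_size: int = 10, sigma_init: float = 0.01,
                 random_state: int = 0):
        self.n_hidden = n_hidden
        self.n_per_class = n_per_class
        self.k = k
        self.epsilon = epsilon
        self.n_updates = n_updates
        self.batch_size = batch_size
        self.sigma_init = sigma_init
        self.random_state = random_state

    def fit(self, X, y):
        X, y_idx = self._setup(X, y)
        rng = np.random.default_rng(self.random_state)
        V = self._joint_visible(X, y_idx)
        rbm = RBMParams(
            W=rng.normal(0.0, self.sigma_init,
                         (self.arch_.n_visible, self.n_hidden)),
            b_v=np.zeros(self.arch_.n_visible), b_h=np.zeros(self.n_hidden))
        for _ in range(self.n_updates):
            batch = V[rng.integers(0, V.shape[0], self.batch_size)]
            rbm = boltzmann.cd_k_update(rbm, batch, k=self.k,
                                        epsilon=self.epsilon, rng_seed=rng)
        self.rbm_ = rbm
        return self


class EventDrivenRBM(_SupervisedRBM):
    """Spiking RBM classifier trained with event-driven CD.

    ``fit`` calibrates (or reuses) the neuron transfer curve, encodes the
    training patterns as clamp currents, and runs the continuous-time
    network with gated-STDP updates for ``n_epochs`` pattern presentations.
    ``predict`` uses the free-energy readout on the learned Boltzmann
    parameters; ``predict_by_sampling`` runs the spiking network and reads
    out the most active class population.

    Parameters
    ----------
    n_hidden, n_per_class : layer sizes of the supervised architecture.
    T, tau_br : half-epoch and burn-in (s) of the gating schedule.
    A, tau_stdp : STDP magnitude (weight units) and window decay (s).
    n_epochs : number of pattern presentations (one per 2T epoch).
    """

    def __init__(self, n_hidden: int = 8, n_per_class: int = 1,
                 T: float = 50e-3, tau_br: float = 10e-3,
                 A: float = 0.02, tau_stdp: float = 4e-3,
                 n_epochs: int = 1500, dt: float = 1e-4,
                 sigma_init: float = 0.1, train_bias: bool = True,
                 neuron: NeuronParams | None = None,
                 transfer_fit: TransferFit | None = None,
                 random_state: int = 0):
        self.n_hidden = n_hidden
        self.n_per_class = n_per_class
        self.T = T
        self.tau_br = tau_br
        self.A = A
        self.tau_stdp = tau_stdp
        self.n_epochs = n_epochs
        self.dt = dt
        self.sigma_init = sigma_init
        self.train_bias = train_bias
        self.neuron = neuron
        self.transfer_fit = transfer_fit
        self.random_state = random_state

    def fit(self, X, y):
        X, y_idx = self._setup(X, y)
        rng = np.random.default_rng(self.random_state)
        np_ = self.neuron or NeuronParams()
        if self.transfer_fit is not None:
            fit = self.transfer_fit
        else:
            fit, _ = calibration.calibrate(np_, rng_seed=self.random_state)
        self.transfer_fit_ = fit
        self.neuron_ = np_
        # visible clamp currents: binarized pixels plus driven label block
        probs = np.where(np.asarray(X) > 0.5, experiments.P_ON,
                         experiments.P_OFF)
        n_items = probs.shape[0]
        currents = np.zeros((n_items, self.arch_.n_visible))
        currents[:, :self.arch_.n_vd] = calibration.inverse_transfer(probs, fit)
        lo = calibration.inverse_transfer(experiments.P_OFF, fit)
        hi = calibration.inverse_transfer(experiments.P_ON, fit)
        currents[:, self.arch_.n_vd:] = lo
        for k, ell in enumerate(y_idx):
            currents[k, self.arch_.label_slice(int(ell))] = hi
        order = rng.integers(0, n_items, self.n_epochs)
        rbm0 = RBMParams(
            W=rng.normal(0.0, self.sigma_init,
                         (self.arch_.n_visible, self.n_hidden)),
            b_v=np.zeros(self.arch_.n_visible), b_h=np.zeros(self.n_hidden))
        sched = GatingSchedule(T=self.T, tau_br=self.tau_br,
                               n_epochs=self.n_epochs)
        cfg = STDPConfig(A=self.A, tau_stdp=self.tau_stdp)
        self.rbm_, self.log_ = ecd.train(
            rbm0, fit, currents, order, sched, cfg, np_, dt=self.dt,
            train_bias=self.train_bias,
            rng_seed=int(rng.integers(0, 2**31 - 1)))
        self.effective_eta_ = ecd.effective_eta(cfg, sched)
        return self

    def predict_by_sampling(self, X, t_run: float = 0.5,
                            window: float | None = None, rng_seed: int = 0):
        """Classify by running the spiking network on each input.

        The sensory units are clamped to the binarized pixels, the class
        units run freely, and the label is the class population with the
        highest rate over the readout window (the last half of the run by
        default).
        """
        check_is_fitted(self, "rbm_")
        X = check_array(X)
        probs = np.where(X > 0.5, experiments.P_ON, experiments.P_OFF)
        sp = calibration.rbm_to_network(self.rbm_, self.transfer_fit_)
        out = []
        window = window if window is not None else t_run / 2
        for k, row in enumerate(probs):
            clamp = np.zeros(self.arch_.n_visible + self.n_hidden)
            clamp[:self.arch_.n_vd] = calibration.inverse_transfer(
                row, self.transfer_fit_)
            st = simulate(self.neuron_, sp, clamp=clamp, t_end=t_run,
                          dt=self.dt, rng_seed=rng_seed + 977 * k)
            idx = experiments.classify_by_rate(st, self.arch_, window)
            out.append(idx)
        out = np.asarray(out)
        res = np.where(out == experiments.UNDECIDED, 0, out)
        return self.classes_[res]

    def generate(self, label, t_run: float = 0.5, rng_seed: int = 0,
                 rescue: bool = False) -> np.ndarray:
        """Generated sensory on-probability image for a class label."""
        check_is_fitted(self, "rbm_")
        ell = int(np.flatnonzero(self.classes_ == label)[0])
        return experiments.generate_from_label(
            self.rbm_, self.arch_, self.transfer_fit_, ell,
            np_=self.neuron_, t_run=t_run, rng_seed=rng_seed, rescue=rescue)
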