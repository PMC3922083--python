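"""Parameter containers for the spiking sampler.

All quantities are in SI units.  The defaults reproduce the reference
software-simulation configuration: a leaky integrate-and-fire neuron with
membrane capacitance ``C = 1 pF``, leak conductance ``g_L = 1 nS`` (membrane
time constant 1 ms), firing threshold ``theta = 100 mV``, reset at 0 V,
absolute refractory period ``tau_r = 4 ms`` and white-noise current of
amplitude ``sigma = 3e-11 A*sqrt(s)``; first-order (alpha-PSP) synapses with
``tau_syn = 4 ms`` and a 1 kHz background Poisson bias train per neuron.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "AbstractNeuronParams",
    "GatingSchedule",
    "STDPConfig",
    "DEFAULT_DT",
]

#: Default integration step (s) of the explicit Euler--Maruyama scheme.
DEFAULT_DT = 1e-4


@dataclass(frozen=True)
class NeuronParams:
    """Physical constants of the stochastic leaky integrate-and-fire neuron.

    The sub-threshold membrane obeys the Langevin equation
    ``C du/dt = -g_L u + I(t) + sigma xi(t)`` with ``u < theta``; on crossing
    ``theta`` the neuron spikes and ``u`` is clamped to ``u_rst`` for
    ``tau_r`` seconds.
    """

    C: float = 1e-12          # membrane capacitance (F)
    g_L: float = 1e-9         # leak conductance (S)
    theta: float = 0.1        # firing threshold (V)
    u_rst: float = 0.0        # reset potential (V)
    tau_r: float = 4e-3       # absolute refractory period (s)
    sigma: float = 3e-11      # white-noise current amplitude (A*sqrt(s))

    def __post_init__(self) -> None:
        if not (self.C > 0 and self.g_L > 0 and self.tau_r > 0):
            raise ValueError("C, g_L and tau_r must be positive")
        if not self.theta > self.u_rst:
            raise ValueError("firing threshold must exceed the reset potential")
        if self.sigma < 0:
            raise ValueError("noise amplitude sigma must be non-negative")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/g_L (s)."""
        return self.C / self.g_L

    @property
    def sigma_V(self) -> float:
        """Effective membrane-potential noise scale sqrt(sigma^2/(g_L C)) (V)."""
        return float(np.sqrt(self.sigma**2 / (self.g_L * self.C)))


@dataclass(frozen=True)
class SynapseParams:
    """First-order current synapses plus the background Poisson bias.

    Each presynaptic spike makes the postsynaptic current jump by
    ``q/tau_syn`` after which it decays exponentially with ``tau_syn``; the
    total charge delivered per spike is therefore ``q``.  ``q[i, j]`` is the
    charge from presynaptic neuron ``i`` onto postsynaptic neuron ``j``.
    ``q_bias[i]`` is the charge per bias-train event onto neuron ``i`` and
    ``nu_bias`` the rate of the (independent, per-neuron) bias trains.
    """

    tau_syn: float = 4e-3
    q: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    q_bias: np.ndarray = field(default_factory=lambda: np.zeros(0))
    nu_bias: float = 1000.0
    #: constant operating-point current per neuron (A); holds a zero-bias
    #: neuron at the sigmoid midpoint so the Poisson train only carries b
    I_offset: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")
        if self.nu_bias < 0:
            raise ValueError("nu_bias must be non-negative")
        q = np.asarray(self.q, dtype=float)
        qb = np.asarray(self.q_bias, dtype=float)
        io = np.asarray(self.I_offset, dtype=float)
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(qb))
                and np.all(np.isfinite(io))):
            raise ValueError("synaptic charges and currents must be finite")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "q_bias", qb)
        object.__setattr__(self, "I_offset", io)

    @property
    def n_neurons(self) -> int:
        return self.q.shape[0]


@dataclass(frozen=True)
class AbstractNeuronParams:
    """Renewal-process reference neuron with exponential hazard.

    A non-refractory neuron fires with instantaneous rate
    ``r(u) = gamma_abs * exp(u)`` where ``u = b + sum_j w_ij psi_j(t)`` and
    ``psi_j`` is the configured PSP trace of neuron ``j`` (a rectangular pulse
    of width ``tau_r``, or a unit-jump exponential of time constant
    ``tau_syn``).  With ``gamma_abs = 1/tau_r`` the stationary occupancy of a
    free unit is the logistic function of ``u``, which is the condition for
    sampling a Boltzmann distribution.
    """

    w: np.ndarray
    b: np.ndarray
    tau_r: float = 4e-3
    psp_shape: str = "alpha"
    tau_syn: float = 4e-3
    gamma_abs: float | None = None   # default 1/tau_r

    def __post_init__(self) -> None:
        if self.tau_r <= 0:
            raise ValueError("tau_r must be positive")
        if self.psp_shape not in ("rectangular", "alpha"):
            raise ValueError("psp_shape must be 'rectangular' or 'alpha'")
        w = np.asarray(self.w, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] != b.size:
            raise ValueError("w must be square and match the bias vector")
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "b", b)

    @property
    def rate_scale(self) -> float:
        """Hazard prefactor gamma_abs (Hz); defaults to 1/tau_r."""
        return 1.0 / self.tau_r if self.gamma_abs is None else self.gamma_abs


@dataclass(frozen=True)
class GatingSchedule:
    """Epoch structure of the gating signal g(t).

    Each 2T epoch holds a data (LTP, g=+1) phase on (tau_br, T) and a
    free-running reconstruction (LTD, g=-1) phase on (T+tau_br, 2T); the
    burn-in windows of length tau_br after each switch carry g=0.
    """

    T: float = 50e-3
    tau_br: float = 10e-3
    n_epochs: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.tau_br < self.T:
            raise ValueError("need 0 < tau_br < T")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be at least 1")


@dataclass(frozen=True)
class STDPConfig:
    """Symmetric exponential STDP used by event-driven contrastive divergence.

    Every spike increments its neuron's eligibility trace by ``A`` (in RBM
    weight units); traces decay with ``tau_stdp``.  A spike on the opposite
    layer commits ``g(t) * trace`` to the shared weight.  Updates are purely
    additive; weights may change sign.
    """

    A: float = 10.0
    tau_stdp: float = 4e-3

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("A must be non-negative (0 disables learning)")
        if self.tau_stdp <= 0:
            raise ValueError("tau_stdp must be positive")


def with_sigma(np_: NeuronParams, sigma: float) -> NeuronParams:
    """Return a copy of ``np_`` with a different noise amplitude."""
    return replace(np_, sigma=sigma)
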