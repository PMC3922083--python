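"""Transfer-function calibration and the RBM <-> network parameter map.

The noisy I&F neuron's stationary rate under constant current follows the
first-passage (Siegert) formula; over a wide range it is well approximated by
the logistic form

    nu(I) = (1/tau_r) * (1 + exp(-beta I) / (gamma tau_r))**-1,

so that the on-probability nu(I) tau_r is a sigmoid in the current.  ``beta``
(1/A) and ``gamma`` (Hz) are obtained by linear regression of
``log(nu^-1 - tau_r)`` on the injected current; they are all that is needed
to translate Boltzmann-machine weights and biases into synaptic charges and
clamp currents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import erfcx

from .boltzmann import RBMParams
from .dynamics import simulate
from .params import DEFAULT_DT, NeuronParams, SynapseParams

__all__ = [
    "TransferFit",
    "analytic_rate",
    "measure_rate",
    "estimate_tau_r",
    "fit_sigmoid",
    "calibrate",
    "rbm_to_network",
    "network_to_rbm",
    "inverse_transfer",
    "transfer_rate",
]

#: Default calibration grid: currents producing rates log-spaced on this range.
FIT_RATE_RANGE = (1.0, 240.0)
FIT_N_POINTS = 20


@dataclass(frozen=True)
class TransferFit:
    """Fitted sigmoid transfer curve of a noisy I&F neuron."""

    beta: float          # exponential slope (1/A)
    gamma: float         # baseline rate (Hz)
    tau_r: float         # refractory period (s)
    fit_residual: float = 0.0   # RMS residual of the log-linear regression
    tau_m: float = float("nan")     # derived membrane time constant (s)
    sigma_V: float = float("nan")   # derived membrane noise scale (V)

    def __post_init__(self) -> None:
        if not (self.beta > 0 and self.gamma > 0 and self.tau_r > 0):
            raise ValueError("beta, gamma and tau_r must be positive")

    @property
    def midpoint_current(self) -> float:
        """Current at which the on-probability is 1/2: -ln(gamma tau_r)/beta."""
        return -np.log(self.gamma * self.tau_r) / self.beta


def transfer_rate(I, fit: TransferFit):
    """Sigmoid transfer curve nu(I) (Hz) for the fitted parameters."""
    I = np.asarray(I, dtype=float)
    return (1.0 / fit.tau_r) / (1.0 + np.exp(-fit.beta * I)
                                / (fit.gamma * fit.tau_r))


def analytic_rate(I: float, np_: NeuronParams) -> float:
    """Stationary firing rate under constant current (diffusion approximation).

    Evaluates the first-passage-time formula

        rate = ( tau_r + tau_m sqrt(pi) * int_{(u_rst-u0)/sigma_V}^{(theta-u0)/sigma_V}
                 exp(x^2) (1 + erf(x)) dx )^-1

    with ``u0 = I/g_L``.  The integrand is computed as ``erfcx(-x)`` so large
    ``|x|`` does not overflow.  Requires ``sigma > 0``.
    """
    if np_.sigma <= 0:
        raise ValueError("analytic_rate requires sigma > 0")
    u0 = I / np_.g_L
    a = (np_.u_rst - u0) / np_.sigma_V
    b = (np_.theta - u0) / np_.sigma_V
    if a > 25.0:
        # exp(a^2) overflows double precision; the rate is indistinguishable
        # from zero at any physical time scale
        return 0.0
    val, err = quad(lambda x: erfcx(-x), a, b, limit=400)
    denom = np_.tau_r + np_.tau_m * np.sqrt(np.pi) * val
    if not np.isfinite(denom) or err > 1e-6 * max(abs(val), 1.0):
        raise ArithmeticError(
            f"quadrature did not converge on [{a:.3g}, {b:.3g}] (err={err:.3g})")
    return 1.0 / denom


def _current_for_rate(rate: float, np_: NeuronParams) -> float:
    """Invert the analytic transfer curve by bisection."""
    from scipy.optimize import brentq
    lo, hi = -1e-6, 1e-4
    while analytic_rate(lo, np_) > rate:
        lo *= 2
    return brentq(lambda I: analytic_rate(I, np_) - rate, lo, hi, xtol=1e-16)


def measure_rate(I: float, np_: NeuronParams, t_sim: float = 5.0,
                 rng_seed: int = 0, dt: float = DEFAULT_DT,
                 transient: float = 0.1) -> float:
    """Firing rate of a single isolated neuron under constant current.

    Simulates for ``t_sim`` seconds (plus a discarded transient, 100 ms by
    default) and returns spike count / t_sim.
    """
    if t_sim <= 0:
        raise ValueError("t_sim must be positive")
    sp = SynapseParams(q=np.zeros((1, 1)), q_bias=np.zeros(1), nu_bias=0.0)
    st = simulate(np_, sp, clamp=np.array([I]), t_end=t_sim + transient,
                  dt=dt, rng_seed=rng_seed)
    return float(np.sum(st.times >= transient) / t_sim)


def estimate_tau_r(np_: NeuronParams, t_sim: float = 5.0,
                   rng_seed: int = 0, dt: float = DEFAULT_DT) -> float:
    """Refractory period as the inverse of the saturated firing rate."""
    # a current driving u far beyond threshold within one membrane time const
    I_max = 50.0 * np_.g_L * (np_.theta - np_.u_rst) + 100.0 * np_.sigma / np.sqrt(dt)
    return 1.0 / measure_rate(I_max, np_, t_sim=t_sim, rng_seed=rng_seed, dt=dt)


def fit_sigmoid(points, tau_r: float, weighting: str = "none") -> TransferFit:
    """Least-squares fit of the sigmoid transfer curve.

    ``points`` is a sequence of (current (A), rate (Hz)) pairs with rates in
    (0, 1/tau_r).  Fits ``log(rate^-1 - tau_r) = -beta I - log(gamma)``.

    With ``weighting="probability"`` each point is weighted by
    ``[P(1-P)]^2`` (P = rate * tau_r), the squared Jacobian between the
    log-domain residual and the on-probability.  This makes the regression
    minimize on-probability error — the quantity that controls sampling
    fidelity — and renders the fit insensitive to how the current grid
    samples the tails.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (current, rate) points")
    I, r = pts[:, 0], pts[:, 1]
    if np.unique(I).size < 2:
        raise ValueError("need at least two distinct currents")
    if np.any(r <= 0) or np.any(r >= 1.0 / tau_r):
        raise ValueError("rates must lie strictly inside (0, 1/tau_r)")
    y = np.log(1.0 / r - tau_r)
    A = np.column_stack([I, np.ones_like(I)])
    if weighting == "probability":
        P = r * tau_r
        w = np.sqrt((P * (1.0 - P)) ** 2)
    elif weighting == "none":
        w = np.ones_like(y)
    else:
        raise ValueError("weighting must be 'none' or 'probability'")
    coef, *_ = np.linalg.lstsq(A * w[:, None], y * w, rcond=None)
    resid = y - A @ coef
    beta = -coef[0]
    gamma = float(np.exp(-coef[1]))
    if beta <= 0:
        raise ValueError("fitted slope is not positive; check the input grid")
    return TransferFit(beta=float(beta), gamma=gamma, tau_r=tau_r,
                       fit_residual=float(np.sqrt(np.mean(resid**2))))


def calibrate(np_: NeuronParams, t_sim: float = 5.0, rng_seed: int = 0,
              dt: float = DEFAULT_DT, rate_range=FIT_RATE_RANGE,
              n_points: int = FIT_N_POINTS, measured: bool = True,
              weighting: str = "probability"):
    """End-to-end calibration of a neuron: returns (TransferFit, grid).

    Chooses currents whose analytic rates are log-spaced over ``rate_range``,
    obtains rates either from simulation (``measured=True``; the protocol a
    hardware system would use) or from the analytic formula, estimates
    ``tau_r`` from the saturated rate, and fits the sigmoid with
    probability-weighted regression (see :func:`fit_sigmoid`).
    """
    targets = np.logspace(np.log10(rate_range[0]), np.log10(rate_range[1]),
                          n_points)
    currents = np.array([_current_for_rate(r, np_) for r in targets])
    if measured:
        rates = np.array([
            measure_rate(I, np_, t_sim=t_sim, rng_seed=rng_seed + 7919 * k, dt=dt)
            for k, I in enumerate(currents)])
        tau_r = estimate_tau_r(np_, t_sim=t_sim, rng_seed=rng_seed + 104729, dt=dt)
    else:
        rates = targets
        tau_r = np_.tau_r
    keep = (rates > 0) & (rates < 1.0 / tau_r)
    fit = fit_sigmoid(np.column_stack([currents[keep], rates[keep]]), tau_r,
                      weighting=weighting)
    fit = TransferFit(beta=fit.beta, gamma=fit.gamma, tau_r=fit.tau_r,
                      fit_residual=fit.fit_residual,
                      tau_m=np_.tau_m, sigma_V=np_.sigma_V)
    return fit, np.column_stack([currents, rates])


def inverse_transfer(p: float, fit: TransferFit):
    """Clamp current producing on-probability ``p`` in a free neuron.

    Inverts ``nu(f) tau_r = p``:  ``f = log(s / (gamma (1 - s tau_r))) / beta``
    with ``s = p / tau_r``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("target probability must lie strictly in (0, 1)")
    s = p / fit.tau_r
    out = np.log(s / (fit.gamma * (1.0 - s * fit.tau_r))) / fit.beta
    return float(out) if out.ndim == 0 else out


def rbm_to_network(rbm: RBMParams, fit: TransferFit,
                   nu_bias: float = 1000.0, tau_syn: float = 4e-3) -> SynapseParams:
    """Map Boltzmann weights/biases onto synaptic charges.

    A presynaptic spike must raise the postsynaptic sigmoid argument by
    ``W`` for one refractory period, which for a first-order synapse means a
    peak PSP current of ``W/beta``, i.e. a charge ``q = W tau_syn / beta``.
    The free neuron must sit at on-probability ``logistic(b)``.  The common
    sigmoid-midpoint offset ``-ln(gamma tau_r)/beta`` is delivered as a
    deterministic operating-point current (``I_offset``), and only the
    Boltzmann bias rides on the Poisson train: ``q_bias = b/(beta nu_bias)``.
    Keeping the Poisson charges small keeps the bias shot noise well below
    the calibrated white-noise amplitude, so the fitted (beta, gamma) remain
    valid during sampling.
    """
    n_v, n_h = rbm.n_visible, rbm.n_hidden
    n = n_v + n_h
    q = np.zeros((n, n))
    q[:n_v, n_v:] = rbm.W * tau_syn / fit.beta
    q[n_v:, :n_v] = rbm.W.T * tau_syn / fit.beta
    b = np.concatenate([rbm.b_v, rbm.b_h])
    I_offset = np.full(n, fit.midpoint_current)
    if nu_bias == 0:
        if np.any(b != 0.0):
            raise ValueError("nu_bias = 0 cannot realize nonzero biases")
        q_bias = np.zeros(n)
    else:
        q_bias = b / (fit.beta * nu_bias)
    return SynapseParams(tau_syn=tau_syn, q=q, q_bias=q_bias,
                         nu_bias=nu_bias, I_offset=I_offset)


def network_to_rbm(sp: SynapseParams, fit: TransferFit, n_visible: int) -> RBMParams:
    """Exact inverse of :func:`rbm_to_network`."""
    W = sp.q[:n_visible, n_visible:] * fit.beta / sp.tau_syn
    b = sp.q_bias * fit.beta * sp.nu_bias
    return RBMParams(W=W, b_v=b[:n_visible], b_h=b[n_visible:])
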