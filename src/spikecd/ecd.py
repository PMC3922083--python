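"""Event-driven contrastive divergence.

Training is folded onto continuous time: every spike triggers an additive,
symmetric STDP update whose sign is set by a slow, zero-mean global gating
signal g(t).  Each epoch of length 2T consists of a data phase (visible layer
clamped, g = +1 after a burn-in tau_br) and a free-running reconstruction
phase (g = -1 after the burn-in).  Averaged over an epoch with uncorrelated
stationary firing, the rule reduces to the contrastive-divergence form
``<dq/dt> = eta (v+ h+ - v- h-)`` with
``eta = 2 A ((T - tau_br)/(2T)) tau_stdp``.

Weights are maintained in Boltzmann (dimensionless) units throughout; the
fixed calibration map converts them to synaptic charges inside the kernel
(a spike's PSP current jump is W/beta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .boltzmann import RBMParams
from .calibration import TransferFit
from .params import GatingSchedule, NeuronParams, STDPConfig

__all__ = [
    "gating",
    "update_traces",
    "stdp_on_spike",
    "effective_eta",
    "train",
    "TrainingLog",
]


def gating(t, sched: GatingSchedule):
    """Gating signal g(t) in {-1, 0, +1}.

    +1 on (tau_br, T) within each 2T epoch (data / LTP phase), -1 on
    (T + tau_br, 2T) (reconstruction / LTD phase), 0 during the burn-in
    windows.  Its integral over any full epoch vanishes.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    m = np.mod(t, 2.0 * sched.T)
    out = np.zeros_like(m)
    out[(m > sched.tau_br) & (m < sched.T)] = 1.0
    out[(m > sched.T + sched.tau_br) & (m < 2.0 * sched.T)] = -1.0
    return int(out) if out.ndim == 0 else out.astype(int)


def update_traces(traces: np.ndarray, fired, dt: float,
                  cfg: STDPConfig) -> np.ndarray:
    """Decay eligibility traces by one step and add spikes.

    Each trace decays by ``exp(-dt/tau_stdp)`` and jumps by ``A`` on its
    neuron's spike, so at any time it equals
    ``A * sum_spikes exp(-(t - t_spike)/tau_stdp)`` exactly (the exponential
    window makes the recursion exact).
    """
    out = traces * np.exp(-dt / cfg.tau_stdp)
    if len(fired):
        out[np.asarray(fired, dtype=int)] += cfg.A
    return out


def stdp_on_spike(W: np.ndarray, layer: str, index: int,
                  opposite_traces: np.ndarray, g_now: int) -> np.ndarray:
    """Commit one spike's gated STDP update to the shared weight matrix.

    A visible spike i adds ``g * trace_h[j]`` to every W[i, j]; a hidden
    spike j adds ``g * trace_v[i]`` to every W[i, j].  The single shared
    matrix serves both directions, so symmetry is preserved by construction.
    The spiker's own trace must not yet include the current spike (pairing
    excludes the zero-lag self term).
    """
    W = np.array(W, dtype=float, copy=True)
    if g_now == 0:
        return W
    if layer == "visible":
        W[index, :] += g_now * opposite_traces
    elif layer == "hidden":
        W[:, index] += g_now * opposite_traces
    else:
        raise ValueError("layer must be 'visible' or 'hidden'")
    return W


def effective_eta(cfg: STDPConfig, sched: GatingSchedule) -> float:
    """Learning rate equivalent of the gated STDP rule:
    eta = 2 A ((T - tau_br)/(2T)) tau_stdp."""
    return 2.0 * cfg.A * ((sched.T - sched.tau_br) / (2.0 * sched.T)) \
        * cfg.tau_stdp


@dataclass(frozen=True)
class TrainingLog:
    """Per-half-epoch trajectory of the spiking training run."""

    epoch: np.ndarray        # epoch index
    g_phase: np.ndarray      # +1 data phase, -1 reconstruction phase
    mean_weight: np.ndarray  # mean of W at the end of the half-epoch
    rate_v: np.ndarray       # visible-layer population rate (Hz)
    rate_h: np.ndarray       # hidden-layer population rate (Hz)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.epoch, self.g_phase,
                                          self.mean_weight, self.rate_v,
                                          self.rate_h]),
                   fmt=["%d", "%d", "%.8e", "%.4f", "%.4f"], delimiter=",",
                   header="epoch,g_phase,mean_weight,rate_v,rate_h")


@njit(cache=True)
def _ecd_kernel(n_v, n_h, n_epochs, steps_T, steps_br, dt,
                n_ref, theta, u_rst, g_over_C, inv_C, noise_amp,
                decay_syn, decay_stdp, inv_beta, tau_syn, lam_bias,
                A, bias_scale, W, bv, bh, I_offset, clamp_currents,
                item_order, train_bias, seed,
                log_mean_w, log_rate_v, log_rate_h):
    """Spiking RBM with online gated-STDP weight updates.

    ``W`` (n_v, n_h), ``bv``, ``bh`` are Boltzmann-unit parameters updated
    in place.  ``clamp_currents[item, i]`` are visible data currents;
    ``item_order[e]`` selects the pattern for epoch ``e``.  A presynaptic
    spike bumps the postsynaptic current by W/beta (bias events by b/beta /
    (nu_bias tau_syn) scaled inside).
    """
    np.random.seed(seed)
    n = n_v + n_h
    u = np.zeros(n)
    I_syn = np.zeros(n)
    jump_next = np.zeros(n)
    k_last = np.full(n, -2**62, dtype=np.int64)
    trace_v = np.zeros(n_v)
    trace_h = np.zeros(n_h)
    trace_b = np.zeros(n)        # bias-train eligibility per neuron
    steps_epoch = 2 * steps_T
    for e in range(n_epochs):
        item = item_order[e]
        for half in range(2):
            cnt_v = 0
            cnt_h = 0
            for s in range(steps_T):
                k = e * steps_epoch + half * steps_T + s
                # gating: zero during burn-in at the start of each half
                if s < steps_br:
                    g = 0.0
                elif half == 0:
                    g = 1.0
                else:
                    g = -1.0
                # synaptic currents: decay then queued jumps
                for i in range(n):
                    I_syn[i] = I_syn[i] * decay_syn + jump_next[i]
                    jump_next[i] = 0.0
                # eligibility traces decay
                for i in range(n_v):
                    trace_v[i] *= decay_stdp
                for j in range(n_h):
                    trace_h[j] *= decay_stdp
                for i in range(n):
                    trace_b[i] *= decay_stdp
                # bias Poisson events: current + bias plasticity + trace
                for i in range(n):
                    nb = np.random.poisson(lam_bias)
                    if nb > 0:
                        b_i = bv[i] if i < n_v else bh[i - n_v]
                        jump_next[i] += nb * b_i * inv_beta \
                            * dt / (lam_bias * tau_syn)
                        if g != 0.0 and train_bias:
                            # neuron's own trace is the pre/post partner;
                            # scaled so the train acts like an always-on unit
                            tr = trace_v[i] if i < n_v else trace_h[i - n_v]
                            if i < n_v:
                                bv[i] += nb * g * tr * bias_scale
                            else:
                                bh[i - n_v] += nb * g * tr * bias_scale
                        trace_b[i] += nb * A * bias_scale
                # membrane update and spikes
                for i in range(n):
                    if k + 1 - k_last[i] < n_ref:
                        u[i] = u_rst
                        continue
                    I_ext = I_offset[i]
                    if half == 0 and i < n_v:
                        I_ext += clamp_currents[item, i]
                    u[i] += dt * (-g_over_C * u[i] + (I_syn[i] + I_ext) * inv_C)
                    u[i] += noise_amp * np.random.normal()
                    if u[i] >= theta:
                        u[i] = u_rst
                        k_last[i] = k + 1
                        if i < n_v:
                            cnt_v += 1
                            # PSPs onto hidden; read traces before own bump
                            for j in range(n_h):
                                jump_next[n_v + j] += W[i, j] * inv_beta
                                if g != 0.0:
                                    W[i, j] += g * trace_h[j]
                            if g != 0.0 and train_bias:
                                bv[i] += g * trace_b[i]
                            trace_v[i] += A
                        else:
                            j = i - n_v
                            cnt_h += 1
                            for ii in range(n_v):
                                jump_next[ii] += W[ii, j] * inv_beta
                                if g != 0.0:
                                    W[ii, j] += g * trace_v[ii]
                            if g != 0.0 and train_bias:
                                bh[j] += g * trace_b[i]
                            trace_h[j] += A
            row = 2 * e + half
            log_mean_w[row] = W.mean()
            log_rate_v[row] = cnt_v / (n_v * steps_T * dt)
            log_rate_h[row] = cnt_h / (n_h * steps_T * dt)
            # guard against runaway updates
            ok = True
            for i in range(n_v):
                for j in range(n_h):
                    if not np.isfinite(W[i, j]):
                        ok = False
            if not ok:
                return e
    return n_epochs


def train(rbm_init: RBMParams, fit: TransferFit, clamp_currents: np.ndarray,
          item_order: np.ndarray, sched: GatingSchedule, cfg: STDPConfig,
          np_: NeuronParams, nu_bias: float = 1000.0, tau_syn: float = 4e-3,
          dt: float = 1e-4, train_bias: bool = True, rng_seed: int = 0):
    """Train a spiking RBM with event-driven CD.

    ``clamp_currents`` has shape (n_items, n_visible): the data currents
    (from ``inverse_transfer`` of the pixel probabilities) driving the
    visible layer during the first half of each epoch.  ``item_order``
    assigns a pattern to every epoch.  Returns the final Boltzmann
    parameters and a :class:`TrainingLog`.
    """
    if cfg.tau_stdp > sched.T / 2:
        raise ValueError("tau_stdp must be much smaller than the half-epoch T")
    n_v, n_h = rbm_init.n_visible, rbm_init.n_hidden
    clamp_currents = np.ascontiguousarray(clamp_currents, dtype=float)
    if clamp_currents.ndim != 2 or clamp_currents.shape[1] != n_v:
        raise ValueError("clamp_currents must be (n_items, n_visible)")
    item_order = np.ascontiguousarray(item_order, dtype=np.int64)
    n_epochs = item_order.size
    if n_epochs != sched.n_epochs:
        sched = GatingSchedule(T=sched.T, tau_br=sched.tau_br,
                               n_epochs=n_epochs)
    steps_T = int(round(sched.T / dt))
    steps_br = int(round(sched.tau_br / dt))
    W = rbm_init.W.copy()
    bv = rbm_init.b_v.copy()
    bh = rbm_init.b_h.copy()
    I_offset = np.full(n_v + n_h, fit.midpoint_current)
    rows = 2 * n_epochs
    log_mean_w = np.zeros(rows)
    log_rate_v = np.zeros(rows)
    log_rate_h = np.zeros(rows)
    done = _ecd_kernel(
        n_v, n_h, n_epochs, steps_T, steps_br, dt,
        int(np.ceil(np_.tau_r / dt - 1e-9)), np_.theta, np_.u_rst,
        np_.g_L / np_.C, 1.0 / np_.C, (np_.sigma / np_.C) * np.sqrt(dt),
        np.exp(-dt / tau_syn), np.exp(-dt / cfg.tau_stdp),
        1.0 / fit.beta, tau_syn, nu_bias * dt,
        cfg.A, 1.0 / (nu_bias * np_.tau_r), W, bv, bh, I_offset,
        clamp_currents, item_order,
        train_bias, int(rng_seed) % (2**31 - 1),
        log_mean_w, log_rate_v, log_rate_h)
    if done < n_epochs:
        raise FloatingPointError(
            f"weights became non-finite during epoch {done}")
    log = TrainingLog(
        epoch=np.repeat(np.arange(n_epochs), 2),
        g_phase=np.tile([1, -1], n_epochs),
        mean_weight=log_mean_w, rate_v=log_rate_v, rate_h=log_rate_h)
    return RBMParams(W=W, b_v=bv, b_h=bh), log
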