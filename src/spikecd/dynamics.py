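"""Continuous-time simulation of the stochastic I&F sampling network.

Two samplers live here.  ``simulate`` integrates the leaky
integrate-and-fire network with white-noise currents, first-order (alpha-PSP)
synapses and per-neuron background Poisson bias trains, using an explicit
Euler--Maruyama scheme (exact exponential decay for the synaptic currents).
``abstract_sample`` runs the renewal-process reference neuron whose hazard is
exponential in the membrane potential; it is the idealised model the I&F
network approximates.

Conventions shared by both kernels:

* a neuron that spiked at time ``s`` is clamped/refractory for updates ending
  strictly before ``s + tau_r``, so the minimum inter-spike interval is
  exactly ``tau_r`` and a saturated neuron fires at ``1/tau_r``;
* all neurons crossing threshold in one step fire in that step and their PSPs
  take effect from the next step onward;
* identical seed and inputs give bitwise-identical spike trains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import DEFAULT_DT, AbstractNeuronParams, NeuronParams, SynapseParams

__all__ = [
    "SpikeTrain",
    "NetworkState",
    "step_network",
    "simulate",
    "poisson_train",
    "abstract_sample",
]


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered list of (time, neuron) spike events on [0, t_end)."""

    times: np.ndarray
    ids: np.ndarray
    n_neurons: int
    t_end: float

    def __post_init__(self) -> None:
        t = np.ascontiguousarray(np.asarray(self.times, dtype=float))
        i = np.ascontiguousarray(np.asarray(self.ids, dtype=np.int64))
        if t.shape != i.shape or t.ndim != 1:
            raise ValueError("times and ids must be matching 1-D arrays")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ids", i)

    def __len__(self) -> int:
        return self.times.size

    def counts(self) -> np.ndarray:
        """Spike count per neuron."""
        return np.bincount(self.ids, minlength=self.n_neurons)

    def rates(self) -> np.ndarray:
        """Mean firing rate per neuron (Hz) over the full duration."""
        return self.counts() / self.t_end

    def neuron(self, i: int) -> np.ndarray:
        """Spike times of neuron ``i``."""
        return self.times[self.ids == i]

    def validate(self, tau_r: float) -> None:
        """Assert the refractory contract: per-neuron ISIs >= tau_r."""
        if np.any(self.times < 0) or np.any(self.times >= self.t_end + 1e-12):
            raise ValueError("spike times outside [0, t_end)")
        for i in range(self.n_neurons):
            ti = self.neuron(i)
            if ti.size > 1 and np.min(np.diff(ti)) < tau_r - 1e-12:
                raise ValueError(f"neuron {i} violates the refractory period")

    # -- plain-text serialization -------------------------------------------
    def to_csv(self, path) -> None:
        header = f"time_s,neuron_id  # n_neurons={self.n_neurons} t_end={self.t_end}"
        np.savetxt(path, np.column_stack([self.times, self.ids]),
                   fmt=["%.9f", "%d"], delimiter=",", header=header)

    @classmethod
    def from_csv(cls, path) -> "SpikeTrain":
        with open(path) as fh:
            header = fh.readline()
        meta = dict(tok.split("=") for tok in header.split() if "=" in tok)
        data = np.loadtxt(path, delimiter=",", ndmin=2)
        if data.size == 0:
            data = np.zeros((0, 2))
        return cls(times=data[:, 0], ids=data[:, 1].astype(np.int64),
                   n_neurons=int(meta["n_neurons"]), t_end=float(meta["t_end"]))

    def to_npz(self, path, **meta) -> None:
        np.savez(path, times=self.times, ids=self.ids,
                 n_neurons=self.n_neurons, t_end=self.t_end, **meta)

    @classmethod
    def from_npz(cls, path) -> "SpikeTrain":
        with np.load(path) as z:
            return cls(times=z["times"], ids=z["ids"],
                       n_neurons=int(z["n_neurons"]), t_end=float(z["t_end"]))


@dataclass
class NetworkState:
    """Mutable state of the I&F network between Euler steps."""

    u: np.ndarray                 # membrane potential (V)
    I_syn: np.ndarray             # filtered recurrent + bias current (A)
    I_data: np.ndarray            # clamp current (A)
    t_last_spike: np.ndarray      # last spike time (s); -inf if never
    t: float = 0.0

    @classmethod
    def zeros(cls, n: int) -> "NetworkState":
        return cls(u=np.zeros(n), I_syn=np.zeros(n), I_data=np.zeros(n),
                   t_last_spike=np.full(n, -np.inf))


def step_network(state: NetworkState, np_: NeuronParams, sp: SynapseParams,
                 spikes_in: np.ndarray, dt: float,
                 rng: np.random.Generator | int | None = None):
    """Advance the network by one Euler--Maruyama step.

    ``spikes_in`` is a per-neuron count of presynaptic events (recurrent
    and/or bias) arriving at the start of this step; each adds
    ``q/tau_syn`` to the corresponding postsynaptic currents.  Returns the
    mutated state and the array of neuron indices that fired.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    bad = ~(np.isfinite(state.u) & np.isfinite(state.I_syn))
    if np.any(bad):
        raise FloatingPointError(
            f"non-finite state in neuron(s) {np.flatnonzero(bad).tolist()}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    n = state.u.size
    spikes_in = np.asarray(spikes_in)
    # synaptic current: exact exponential decay, then incoming jumps
    state.I_syn *= np.exp(-dt / sp.tau_syn)
    if sp.q.size:
        state.I_syn += spikes_in @ sp.q / sp.tau_syn
    t_next = state.t + dt
    refractory = (t_next - state.t_last_spike) < np_.tau_r
    free = ~refractory
    noise = (np_.sigma / np_.C) * np.sqrt(dt) * rng.standard_normal(n)
    I_const = sp.I_offset if np.asarray(sp.I_offset).size else 0.0
    du = dt * (-np_.g_L * state.u + state.I_syn + state.I_data + I_const) / np_.C
    state.u[free] += du[free] + noise[free]
    state.u[refractory] = np_.u_rst
    fired = np.flatnonzero(free & (state.u >= np_.theta))
    state.u[fired] = np_.u_rst
    state.t_last_spike[fired] = t_next
    state.t = t_next
    return state, fired


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lif_kernel(n, n_steps, dt, tau_r, theta, u_rst, g_over_C, inv_C,
                noise_amp, decay, q_jump, q_bias_jump, lam_bias,
                clamp_edges, clamp_currents, seed,
                rec_times, rec_ids):
    """Integrate the full I&F network; returns the number of spikes recorded."""
    np.random.seed(seed)
    u = np.zeros(n)
    I_syn = np.zeros(n)
    k_last = np.full(n, -2**62, dtype=np.int64)   # step index of last spike
    n_ref = int(np.ceil(tau_r / dt - 1e-9))       # steps covered by tau_r
    jump_next = np.zeros(n)          # PSP jumps landing at the next step
    n_rec = 0
    seg = 0
    n_seg = clamp_edges.size
    for k in range(n_steps):
        t = k * dt
        while seg + 1 < n_seg and t >= clamp_edges[seg + 1] - 1e-12:
            seg += 1
        for i in range(n):
            I_syn[i] = I_syn[i] * decay + jump_next[i]
            jump_next[i] = 0.0
            if lam_bias > 0.0:
                nb = np.random.poisson(lam_bias)
                if nb > 0:
                    jump_next[i] += nb * q_bias_jump[i]
        for i in range(n):
            if k + 1 - k_last[i] < n_ref:
                u[i] = u_rst
            else:
                u[i] += dt * (-g_over_C * u[i]
                              + (I_syn[i] + clamp_currents[seg, i]) * inv_C)
                if noise_amp > 0.0:
                    u[i] += noise_amp * np.random.normal()
                if u[i] >= theta:
                    u[i] = u_rst
                    k_last[i] = k + 1
                    if n_rec < rec_times.size:
                        rec_times[n_rec] = (k + 1) * dt
                        rec_ids[n_rec] = i
                        n_rec += 1
                    for jj in range(n):
                        jump_next[jj] += q_jump[i, jj]
    return n_rec


def _as_clamp_schedule(clamp, n: int, t_end: float):
    """Normalize a clamp spec to (edges, currents) piecewise-constant form.

    Accepts ``None``, a scalar, an (n,) constant vector, or a tuple
    ``(edges, currents)`` with ``edges`` the segment start times (first must
    be 0) and ``currents`` of shape (n_segments, n).
    """
    if clamp is None:
        return np.zeros(1), np.zeros((1, n))
    if isinstance(clamp, tuple):
        edges, currents = clamp
        edges = np.asarray(edges, dtype=float)
        currents = np.atleast_2d(np.asarray(currents, dtype=float))
        if edges[0] != 0.0:
            raise ValueError("clamp schedule must start at t=0")
        if currents.shape != (edges.size, n):
            raise ValueError("clamp currents must have shape (n_segments, n)")
        return edges, currents
    arr = np.broadcast_to(np.asarray(clamp, dtype=float), (n,)).copy()
    return np.zeros(1), arr[None, :]


def simulate(np_: NeuronParams, sp: SynapseParams, clamp=None,
             t_end: float = 1.0, dt: float = DEFAULT_DT,
             rng_seed: int = 0) -> SpikeTrain:
    """Simulate the noisy I&F network and return its spike train.

    ``clamp`` is a per-neuron data-current schedule (see
    :func:`_as_clamp_schedule`).  The run is bitwise reproducible for a given
    seed.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = sp.n_neurons if sp.n_neurons else np.atleast_1d(
        np.asarray(sp.q_bias, dtype=float)).size
    if n == 0:
        n = 1
    q = np.zeros((n, n)) if sp.q.size == 0 else np.asarray(sp.q, dtype=float)
    q_bias = np.broadcast_to(np.asarray(sp.q_bias, dtype=float), (n,)).copy() \
        if np.asarray(sp.q_bias).size else np.zeros(n)
    edges, currents = _as_clamp_schedule(clamp, n, t_end)
    if np.asarray(sp.I_offset).size:
        currents = currents + np.broadcast_to(
            np.asarray(sp.I_offset, dtype=float), (n,))[None, :]
    n_steps = int(round(t_end / dt))
    cap = max(1024, int(1.05 * n * n_steps * dt / np_.tau_r) + 64)
    rec_times = np.empty(cap)
    rec_ids = np.empty(cap, dtype=np.int64)
    n_rec = _lif_kernel(
        n, n_steps, dt, np_.tau_r, np_.theta, np_.u_rst,
        np_.g_L / np_.C, 1.0 / np_.C,
        (np_.sigma / np_.C) * np.sqrt(dt), np.exp(-dt / sp.tau_syn),
        q / sp.tau_syn, q_bias / sp.tau_syn, sp.nu_bias * dt,
        edges, currents, int(rng_seed) % (2**31 - 1),
        rec_times, rec_ids)
    return SpikeTrain(times=rec_times[:n_rec].copy(), ids=rec_ids[:n_rec].copy(),
                      n_neurons=n, t_end=t_end)


def poisson_train(rate: float, t_end: float, rng_seed: int = 0) -> SpikeTrain:
    """A homogeneous Poisson spike train on [0, t_end)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(rng_seed)
    times = np.empty(0)
    if rate > 0:
        n = rng.poisson(rate * t_end)
        times = np.sort(rng.uniform(0.0, t_end, size=n))
    return SpikeTrain(times=times, ids=np.zeros(times.size, dtype=np.int64),
                      n_neurons=1, t_end=t_end)


@njit(cache=True)
def _abstract_kernel(n, n_steps, dt, tau_r, rate_scale, rect_psp, decay,
                     w, b, u_clamp_on, u_clamp, seed, rec_times, rec_ids):
    """Renewal-process sampler.  Firing prob per step is 1 - exp(-r(u) dt)."""
    np.random.seed(seed)
    psi = np.zeros(n)            # PSP trace per neuron
    k_last = np.full(n, -2**62, dtype=np.int64)
    n_ref = int(np.ceil(tau_r / dt - 1e-9))
    jump_next = np.zeros(n)
    n_rec = 0
    for k in range(n_steps):
        t_next = (k + 1) * dt
        for j in range(n):
            if rect_psp:
                # the box [s, s + tau_r) overlaps this update interval
                psi[j] = 1.0 if (k + 1 - k_last[j]) <= n_ref else 0.0
            else:
                psi[j] = psi[j] * decay + jump_next[j]
                jump_next[j] = 0.0
        for i in range(n):
            if k + 1 - k_last[i] < n_ref:
                continue
            if u_clamp_on[i]:
                u = u_clamp[i]
            else:
                u = b[i]
                for j in range(n):
                    u += w[j, i] * psi[j]
            lam = rate_scale * np.exp(u) * dt
            if lam > 1e3:
                # hazard this extreme means the configuration (or dt) is
                # pathological; the Bernoulli step itself stays exact
                raise ValueError("dt too coarse for the encountered potentials")
            if np.random.random() < -np.expm1(-lam):
                k_last[i] = k + 1
                if n_rec < rec_times.size:
                    rec_times[n_rec] = t_next
                    rec_ids[n_rec] = i
                    n_rec += 1
                if rect_psp:
                    psi[i] = 1.0
                else:
                    jump_next[i] += 1.0
    return n_rec


def abstract_sample(ap: AbstractNeuronParams, t_end: float,
                    dt: float = 2e-5, rng_seed: int = 0,
                    u_clamp: np.ndarray | None = None) -> SpikeTrain:
    """Sample the abstract (renewal-process) network.

    Each non-refractory neuron fires in a step of length ``dt`` with
    probability ``1 - exp(-r(u) dt)``, ``r(u) = gamma_abs exp(u)``, where the
    membrane potential is the linear sum of bias and weighted PSP traces.
    ``u_clamp`` optionally pins the potential of selected neurons (NaN =
    unclamped), which drives them like external data would.
    """
    if t_end <= 0 or dt <= 0:
        raise ValueError("t_end and dt must be positive")
    n = ap.b.size
    n_steps = int(round(t_end / dt))
    if u_clamp is None:
        clamp_on = np.zeros(n, dtype=np.bool_)
        clamp_val = np.zeros(n)
    else:
        u_clamp = np.asarray(u_clamp, dtype=float)
        clamp_on = ~np.isnan(u_clamp)
        clamp_val = np.where(clamp_on, u_clamp, 0.0)
    cap = max(1024, int(1.05 * n * t_end / ap.tau_r) + 64)
    rec_times = np.empty(cap)
    rec_ids = np.empty(cap, dtype=np.int64)
    n_rec = _abstract_kernel(
        n, n_steps, dt, ap.tau_r, ap.rate_scale,
        ap.psp_shape == "rectangular", np.exp(-dt / ap.tau_syn),
        np.ascontiguousarray(ap.w), np.ascontiguousarray(ap.b),
        clamp_on, clamp_val, int(rng_seed) % (2**31 - 1),
        rec_times, rec_ids)
    return SpikeTrain(times=rec_times[:n_rec].copy(), ids=rec_ids[:n_rec].copy(),
                      n_neurons=n, t_end=t_end)
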