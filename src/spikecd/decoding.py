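"""Spike-train decoding and sampling-quality metrics.

Each neuron is read out as a binary random variable that is 1 for one
refractory period after each spike.  Sampling this indicator on a regular
clock (1 kHz by default, so a 4 ms refractory period covers exactly four
ticks) turns a spike raster into a sequence of binary network states, whose
add-one-smoothed histogram is compared to the exactly enumerated Boltzmann
distribution by KL divergence (natural log, nats).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boltzmann import RBMParams, StateDistribution, exact_distribution
from .dynamics import SpikeTrain

__all__ = [
    "StateTrace",
    "spikes_to_states",
    "empirical_distribution",
    "kl_divergence",
    "kl_vs_time",
]

#: Burn-in discarded from the start of every sampling run before histogramming.
DEFAULT_BURN_IN = 10e-3


@dataclass(frozen=True)
class StateTrace:
    """Binary network states on a regular sample clock."""

    times: np.ndarray      # tick times (s)
    states: np.ndarray     # (n_ticks, n_neurons) in {0, 1}
    sample_rate: float     # Hz

    @property
    def n_neurons(self) -> int:
        return self.states.shape[1]

    def codes(self) -> np.ndarray:
        """Integer encoding of each state row (unit 0 is the LSB)."""
        weights = (1 << np.arange(self.n_neurons)).astype(np.int64)
        return self.states.astype(np.int64) @ weights


def spikes_to_states(spikes: SpikeTrain, tau_r: float,
                     sample_rate: float = 1000.0) -> StateTrace:
    """Box-extend each spike by ``tau_r`` and sample the indicator.

    A spike at time ``s`` sets its neuron's state to 1 at every clock tick in
    ``[s, s + tau_r)``; equivalently a neuron is 1 at tick ``t`` iff it
    spiked in ``(t - tau_r, t]``.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    dt = 1.0 / sample_rate
    n_ticks = int(np.floor(spikes.t_end / dt)) + 1
    states = np.zeros((n_ticks, spikes.n_neurons), dtype=np.uint8)
    if len(spikes):
        first = np.ceil(spikes.times / dt - 1e-9).astype(np.int64)
        last = np.ceil((spikes.times + tau_r) / dt - 1e-9).astype(np.int64)
        width = int(np.max(last - first)) if len(spikes) else 0
        for off in range(width):
            ticks = first + off
            ok = (ticks < last) & (ticks < n_ticks)
            states[ticks[ok], spikes.ids[ok]] = 1
    times = np.arange(n_ticks) * dt
    return StateTrace(times=times, states=states, sample_rate=sample_rate)


def empirical_distribution(trace: StateTrace, add_one: bool = True,
                           burn_in: float = DEFAULT_BURN_IN,
                           t_max: float | None = None) -> StateDistribution:
    """Histogram of joint states, optionally add-one smoothed.

    Ticks before ``burn_in`` (and at or after ``t_max``, if given) are
    discarded.  With ``add_one`` every one of the 2^N states gets one
    phantom count, avoiding zero probabilities in KL computations.
    """
    n = trace.n_neurons
    if n > 20:
        raise ValueError("joint histogram limited to 20 neurons")
    keep = trace.times >= burn_in
    if t_max is not None:
        keep &= trace.times < t_max
    codes = trace.codes()[keep]
    counts = np.bincount(codes, minlength=2**n).astype(float)
    if add_one:
        counts += 1.0
    total = counts.sum()
    if total == 0:
        raise ValueError("no ticks left after burn-in")
    return StateDistribution(p=counts / total, n_units=n)


def kl_divergence(p: StateDistribution | np.ndarray,
                  q: StateDistribution | np.ndarray) -> float:
    """Kullback-Leibler divergence D(p || q) in nats."""
    pa = p.p if isinstance(p, StateDistribution) else np.asarray(p, dtype=float)
    qa = q.p if isinstance(q, StateDistribution) else np.asarray(q, dtype=float)
    if pa.shape != qa.shape:
        raise ValueError("distributions must share the same support")
    mask = pa > 0
    if np.any(qa[mask] <= 0):
        raise ValueError("q must be positive wherever p is positive")
    return float(np.sum(pa[mask] * np.log(pa[mask] / qa[mask])))


def kl_vs_time(spikes: SpikeTrain, rbm: RBMParams, checkpoints,
               tau_r: float = 4e-3, sample_rate: float = 1000.0,
               burn_in: float = DEFAULT_BURN_IN,
               marginal_visible: bool = False) -> list[tuple[float, float]]:
    """KL(empirical up to t || exact) at each checkpoint time.

    Uses add-one smoothing on the joint 2^N histogram (or the visible
    marginal if requested).
    """
    checkpoints = list(checkpoints)
    if any(b > a for a, b in zip(checkpoints[1:], checkpoints)):
        raise ValueError("checkpoints must be increasing")
    exact = exact_distribution(rbm)
    if marginal_visible:
        exact = exact.marginal(range(rbm.n_visible))
    trace = spikes_to_states(spikes, tau_r, sample_rate)
    out = []
    for t in checkpoints:
        emp = empirical_distribution(trace, add_one=True, burn_in=burn_in,
                                     t_max=t)
        if marginal_visible:
            emp = emp.marginal(range(rbm.n_visible))
        out.append((t, kl_divergence(emp, exact)))
    return out
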