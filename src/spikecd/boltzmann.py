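"""Exact reference machinery for restricted Boltzmann machines.

Energies, exact enumeration of the Boltzmann distribution on small networks,
block Gibbs sampling, free energies, the standard CD-k parameter update and
uniform weight discretization.  Everything here operates on dimensionless
Boltzmann parameters; the spiking network is mapped onto these via the
calibration module.

Energy convention (bipartite, each pair counted once):

    E(v, h) = -v^T W h - b_v^T v - b_h^T h
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RBMParams",
    "StateDistribution",
    "random_rbm",
    "energy",
    "all_states",
    "exact_distribution",
    "gibbs_sample",
    "free_energy",
    "cd_k_update",
    "discretize",
]

ENUM_GUARD = 20     # largest N_v + N_h allowed for exact enumeration


@dataclass(frozen=True)
class RBMParams:
    """Weights and biases of a restricted Boltzmann machine.

    The bipartite structure (no couplings within a layer) is enforced by
    construction: only the visible-by-hidden block ``W`` exists.
    """

    W: np.ndarray
    b_v: np.ndarray
    b_h: np.ndarray

    def __post_init__(self) -> None:
        W = np.atleast_2d(np.asarray(self.W, dtype=float))
        b_v = np.atleast_1d(np.asarray(self.b_v, dtype=float))
        b_h = np.atleast_1d(np.asarray(self.b_h, dtype=float))
        if W.shape != (b_v.size, b_h.size):
            raise ValueError("W must be (n_visible, n_hidden)")
        if not np.all(np.isfinite(W)):
            raise ValueError("weights must be finite")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "b_v", b_v)
        object.__setattr__(self, "b_h", b_h)

    @property
    def n_visible(self) -> int:
        return self.b_v.size

    @property
    def n_hidden(self) -> int:
        return self.b_h.size

    @property
    def n_units(self) -> int:
        return self.n_visible + self.n_hidden

    def save_npz(self, path, **meta) -> None:
        np.savez(path, W=self.W, b_v=self.b_v, b_h=self.b_h, **meta)

    @classmethod
    def load_npz(cls, path) -> "RBMParams":
        with np.load(path) as z:
            return cls(W=z["W"], b_v=z["b_v"], b_h=z["b_h"])


@dataclass(frozen=True)
class StateDistribution:
    """A probability table over all 2^n binary states (LSB = unit 0)."""

    p: np.ndarray
    n_units: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.size != 2**self.n_units:
            raise ValueError("probability table must have 2^n_units entries")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "p", p)

    def marginal(self, units) -> "StateDistribution":
        """Marginal distribution over the listed unit indices."""
        units = list(units)
        idx = np.arange(self.p.size)
        code = np.zeros(self.p.size, dtype=np.int64)
        for pos, u in enumerate(units):
            code |= ((idx >> u) & 1) << pos
        return StateDistribution(
            p=np.bincount(code, weights=self.p, minlength=2**len(units)),
            n_units=len(units))


def random_rbm(n_visible: int = 5, n_hidden: int = 5,
               rng: np.random.Generator | int | None = None,
               w_loc: float = -0.75, w_scale: float = 1.5,
               b_loc: float = -1.5, b_scale: float = 0.5) -> RBMParams:
    """Draw an RBM from the validation-study parameter distributions.

    Defaults: W ~ N(-0.75, 1.5), biases ~ N(-1.5, 0.5) (scale = std).
    """
    rng = np.random.default_rng(rng)
    return RBMParams(W=rng.normal(w_loc, w_scale, size=(n_visible, n_hidden)),
                     b_v=rng.normal(b_loc, b_scale, size=n_visible),
                     b_h=rng.normal(b_loc, b_scale, size=n_hidden))


def _check_binary(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if not np.all((x == 0) | (x == 1)):
        raise ValueError("state entries must be binary (0/1)")
    return x.astype(float)


def energy(state: np.ndarray, rbm: RBMParams) -> float:
    """Energy of a full binary state vector [v, h]."""
    state = _check_binary(state)
    if state.size != rbm.n_units:
        raise ValueError("state length must be n_visible + n_hidden")
    v, h = state[:rbm.n_visible], state[rbm.n_visible:]
    return float(-v @ rbm.W @ h - rbm.b_v @ v - rbm.b_h @ h)


def all_states(n: int) -> np.ndarray:
    """All 2^n binary vectors; row k is the bits of k, LSB = unit 0."""
    idx = np.arange(2**n)
    return ((idx[:, None] >> np.arange(n)[None, :]) & 1).astype(float)


def exact_distribution(rbm: RBMParams) -> StateDistribution:
    """Exact Boltzmann distribution over all joint states (small RBMs only)."""
    n = rbm.n_units
    if n > ENUM_GUARD:
        raise ValueError(f"exact enumeration limited to {ENUM_GUARD} units")
    S = all_states(n)
    V, H = S[:, :rbm.n_visible], S[:, rbm.n_visible:]
    E = -np.einsum("ki,ij,kj->k", V, rbm.W, H) - V @ rbm.b_v - H @ rbm.b_h
    logp = -E - np.max(-E)
    p = np.exp(logp)
    return StateDistribution(p=p / p.sum(), n_units=n)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def gibbs_sample(rbm: RBMParams, n_steps: int,
                 rng_seed: int | np.random.Generator = 0,
                 v0: np.ndarray | None = None):
    """Block Gibbs chain; returns (V, H) state sequences of length n_steps.

    One step samples all hidden units given v, then all visible units given
    h: P(h_j=1|v) = logistic(b_h_j + sum_i W_ij v_i) and symmetrically.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    rng = np.random.default_rng(rng_seed) \
        if not isinstance(rng_seed, np.random.Generator) else rng_seed
    v = (np.zeros(rbm.n_visible) if v0 is None
         else _check_binary(v0).astype(float))
    V = np.empty((n_steps, rbm.n_visible))
    H = np.empty((n_steps, rbm.n_hidden))
    for k in range(n_steps):
        ph = _sigmoid(rbm.b_h + v @ rbm.W)
        h = (rng.random(rbm.n_hidden) < ph).astype(float)
        pv = _sigmoid(rbm.b_v + rbm.W @ h)
        v = (rng.random(rbm.n_visible) < pv).astype(float)
        V[k], H[k] = v, h
    return V, H


def free_energy(v: np.ndarray, rbm: RBMParams) -> float:
    """Free energy of a visible configuration, hidden layer marginalized.

    F(v) = -b_v^T v - sum_j log(1 + exp(b_h_j + sum_i W_ij v_i)), so that
    exp(-F(v)) = sum_h exp(-E(v, h)).
    """
    v = _check_binary(v)
    x = rbm.b_h + v @ rbm.W
    return float(-rbm.b_v @ v - np.sum(np.logaddexp(0.0, x)))


def cd_k_update(rbm: RBMParams, data_batch: np.ndarray, k: int = 1,
                epsilon: float = 1e-3,
                rng_seed: int | np.random.Generator = 0) -> RBMParams:
    """One standard CD-k parameter update from a batch of visible vectors.

    Data-phase statistics use the exact conditional hidden probabilities
    given the clamped data; the reconstruction phase runs k alternating
    block-Gibbs steps and again uses conditional probabilities for the
    statistics (Rao-Blackwellised pairwise terms).  Biases are updated from
    the <v> and <h> differences.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    rng = np.random.default_rng(rng_seed) \
        if not isinstance(rng_seed, np.random.Generator) else rng_seed
    V0 = np.atleast_2d(_check_binary(data_batch))
    ph0 = _sigmoid(rbm.b_h + V0 @ rbm.W)
    # alternating chain started from the data
    h = (rng.random(ph0.shape) < ph0).astype(float)
    for _ in range(k):
        pv = _sigmoid(rbm.b_v + h @ rbm.W.T)
        v = (rng.random(pv.shape) < pv).astype(float)
        ph = _sigmoid(rbm.b_h + v @ rbm.W)
        h = (rng.random(ph.shape) < ph).astype(float)
    m = V0.shape[0]
    dW = (V0.T @ ph0 - v.T @ ph) / m
    db_v = (V0 - v).mean(axis=0)
    db_h = (ph0 - ph).mean(axis=0)
    return RBMParams(W=rbm.W + epsilon * dW,
                     b_v=rbm.b_v + epsilon * db_v,
                     b_h=rbm.b_h + epsilon * db_h)


def _snap(x: np.ndarray, n_bits: int, stats=None) -> np.ndarray:
    mu, sd = (float(np.mean(x)), float(np.std(x))) if stats is None else stats
    if sd == 0.0:
        return x.copy()
    lo, hi = mu - 4.5 * sd, mu + 4.5 * sd
    levels = np.linspace(lo, hi, 2**n_bits)
    idx = np.clip(np.round((x - lo) / (hi - lo) * (2**n_bits - 1)),
                  0, 2**n_bits - 1).astype(int)
    out = levels[idx]
    # projection property: an input already on the grid is returned unchanged
    if np.allclose(out, x, rtol=0, atol=1e-15 * max(abs(lo), abs(hi), 1.0)):
        return x.copy()
    return out


def discretize(rbm: RBMParams, n_bits: int, stats=None) -> RBMParams:
    """Snap weights and biases to 2^n_bits uniform levels per parameter group.

    Levels span (mu - 4.5 sd, mu + 4.5 sd) of each group (weights, visible
    biases, hidden biases); values outside clip to the end levels.  By
    default mu and sd are the statistics of the input group; passing
    ``stats`` = ((mu, sd), (mu, sd), (mu, sd)) pins the grid, which makes the
    operation an exact projection (idempotent under a fixed grid).
    """
    if n_bits < 1:
        raise ValueError("n_bits must be at least 1")
    sw, sv, sh = stats if stats is not None else (None, None, None)
    return RBMParams(W=_snap(rbm.W, n_bits, sw),
                     b_v=_snap(rbm.b_v, n_bits, sv),
                     b_h=_snap(rbm.b_h, n_bits, sh))
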