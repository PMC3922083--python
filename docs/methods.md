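# Methods

This note documents the models implemented in `spikecd`, the parameter
conventions, the numerical choices, and what the synthetic validation does
and does not establish.

## 1. The sampling model

### Abstract neuron

The reference sampler is a renewal process: a non-refractory neuron with
membrane potential `u` fires with hazard `r(u) = γ_abs · exp(u)` and is then
absolutely refractory for `τ_r`.  The binary variable `z` attached to the
neuron is 1 for `τ_r` after each spike.  With `γ_abs = 1/τ_r` (the default;
`γ_abs` is exposed because the dimensional convention of the exponential
hazard is not unique) the stationary occupancy of a free unit is

    P(z = 1) = r τ_r / (1 + r τ_r) = logistic(u),

which is the condition for the network state to be an MCMC chain over the
Boltzmann distribution of `E(z) = −½ Σ w_ij z_i z_j − Σ b_i z_i` when
`u_i = b_i + Σ_j w_ij z_j(t)` with rectangular PSPs (each presynaptic spike
contributes `w_ij` for exactly `τ_r`).

Hardware-realistic synapses are first-order filters, so the package's
default PSP is "alpha" shaped: each spike adds a unit jump to a trace that
decays with `τ_syn`.  With `τ_syn = τ_r` the trace has the same time
integral per spike as the rectangular box, and at stationary rate ν its
mean is `ν τ_r = P(z=1)`, so means map correctly; the mismatch in the
*shape* (exponential tails overlapping instead of hard boxes) is the main
source of residual sampling error and is why even the abstract sampler
with alpha PSPs plateaus at a nonzero KL.

### Noisy integrate-and-fire neuron

The spiking implementation replaces the abstract hazard by a leaky I&F
neuron with white-noise current,

    C du/dt = −g_L u + I(t) + σ ξ(t),   u < θ,

with spike at `θ`, reset to `u_rst`, refractory `τ_r`.  Defaults (all SI):
`C = 1 pF`, `g_L = 1 nS` (so `τ_m = 1 ms`), `θ = 0.1 V`, `u_rst = 0`,
`τ_r = 4 ms`, `σ = 3·10⁻¹¹ A·√s`, `τ_syn = 4 ms`, bias Poisson rate
`ν_bias = 1 kHz`.  Its stationary transfer function is the first-passage
formula (implemented as `analytic_rate` via `erfcx` to avoid overflow),
and because `(θ − u_rst)/σ_V ≈ 0.105` is small the curve is close to a
logistic in the input current:

    ν(I) ≈ (1/τ_r) (1 + exp(−βI)/(γ τ_r))⁻¹.

## 2. Calibration and the parameter map

`calibrate` measures rates at 20 currents whose stationary rates are
log-spaced over [1, 240] Hz (5 s per point, first 100 ms discarded),
estimates `τ_r` as the inverse saturated rate, and fits
`log(ν⁻¹ − τ_r) = −βI − log γ` by least squares.

Two details matter and were chosen deliberately:

- **Probability weighting.**  The plain log-domain regression is dominated
  by the low-rate tail, where the true curve is Gaussian rather than
  exponential in `I`; the fitted midpoint then misses the real
  half-occupancy current by ~0.1 in probability, which is fatal for
  sampling fidelity.  The default regression therefore weights each point
  by `[P(1−P)]²` (`P = ν τ_r`), the squared Jacobian from log-domain
  residual to occupancy error.  This makes the fit minimize occupancy
  error, and makes it insensitive to how the grid samples the tails
  (max occupancy error ~0.05 across grids, versus ~0.19 unweighted).
- **Measured, not analytic, rates.**  The network is later simulated at
  `dt = 0.1 ms`; discrete-time threshold detection has an `O(√dt)`
  first-passage deficit (−10…−40% depending on the operating point), so
  calibrating on simulated rates at the same `dt` keeps calibration and
  operation self-consistent.  The recovered constants therefore describe
  *this simulator at this step*, not the `dt → 0` formula; with the
  default protocol `β ≈ 2.6·10⁹ A⁻¹` and `γ ≈ 2.6·10³ Hz`.

The map from Boltzmann parameters to network parameters follows from
requiring that a fully-on presynaptic unit (rate `1/τ_r`) raise the
postsynaptic sigmoid argument `βI` by `W`:

- synaptic charge per spike `q = W τ_syn / β` (peak PSP current `W/β`);
- a constant operating-point current `I₀ = −ln(γ τ_r)/β` holds a zero-bias
  unit at occupancy ½;
- the Boltzmann bias rides on the Poisson bias train,
  `q_bias = b/(β ν_bias)`.

Splitting the bias this way (constant midpoint current + small Poisson
charges) keeps the bias shot noise well below the calibrated white noise
`σ`; delivering the full offset through the Poisson train would add shot
noise larger than `σ` itself and visibly flatten the effective transfer
curve.  Clamp ("data") currents come from inverting the fitted sigmoid:
`f = β⁻¹ log(s/(γ(1 − s τ_r)))`, `s = p/τ_r`.

## 3. Decoding and validation

Each spike is extended into a box of length `τ_r` and the resulting binary
vector is sampled at 1 kHz (a 4 ms box covers exactly 4 ticks); the first
10 ms of every run are discarded as burn-in.  Occurrences of all `2^N`
joint states are counted with one added phantom count per state (so the KL
divergence, natural log, is always finite).  Validation draws RBMs with
`W ~ N(−0.75, 1.5²)` and biases `~ N(−1.5, 0.5²)` — deliberately strong
weights, a hard test for an approximate sampler — and compares against
exact enumeration, with block Gibbs sampling (one sweep identified with
one `τ_r`) as the conventional baseline.

At the validation scale used by the tests and the acceptance script
(12 instances × 300 s; chosen to keep a full run in minutes on one CPU)
the I&F sampler reaches mean KL ≈ 0.05–0.07 nats and the abstract sampler
with alpha PSPs ≈ 0.05; both plateau (the error is approximation bias,
not sampling noise, which at 3·10⁵ ticks contributes only ~2·10⁻³ nats).

## 4. Event-driven contrastive divergence

Weight updates are additive, polarity-free, and triggered by every spike:
a spike in one layer commits `g(t) ×` (opposite layer's eligibility
trace) to the shared weight matrix, where traces jump by `A` on their
neuron's spikes and decay with `τ_STDP = 4 ms`.  The gating signal is +1
during `(τ_br, T)` of each `2T = 100 ms` epoch (visible layer clamped to a
pattern), −1 during `(T + τ_br, 2T)` (free reconstruction), and 0 in the
`τ_br = 10 ms` burn-ins, so its epoch integral is exactly zero.  Traces
are causal and are read *before* the spiker's own trace increments, so a
spike pair with lag Δ is committed once with weight `A·e^{−|Δ|/τ_STDP}`;
under frozen uncorrelated Poisson activity the epoch-averaged drift is
then exactly `η (v̄⁺h̄⁺ − v̄⁻h̄⁻)` with `η = 2A ((T − τ_br)/2T) τ_STDP`
(verified to 3 standard errors in the tests).

Biases are trained by the same gated rule with the neuron's own
1 kHz bias train as the presynaptic partner, scaled by `1/(ν_bias τ_r)` so
the train is equivalent to an always-on partner unit; this reproduces the
standard CD bias gradient `ε(⟨v⟩₊ − ⟨v⟩₋)` in expectation.  Weights are
maintained in Boltzmann units inside the training kernel and converted to
charges on the fly, so the calibration map stays exact during learning.

Training hyperparameters for the reduced task (16 pixels, 2 labels,
8 hidden units, 1500 epochs): `A = 0.02`.  Larger magnitudes make the
online updates outrun the sampler — weights grow past `|W| ≈ 5`, where
the alpha-PSP approximation degrades and the visible layer collapses —
so the default is deliberately conservative.  There is no weight decay or
clipping; a non-finite guard aborts with the epoch index.

## 5. Functional tasks

The supervised architecture splits the visible layer into sensory units
and `n_per_class` neurons per label (multiple neurons per label keep
per-synapse weights, and hence spike-to-spike correlations, small — a
single label neuron saturates at 250 Hz and synchronizes its targets).
Recognition reads out either the most active class population in a
sampling run or the free-energy argmin (ties broken toward the lowest
label, for determinism).  Generation clamps one label population to the
0.98-occupancy current, suppresses the others with the 10⁻⁵ current, and
reads the sensory rates × `τ_r` after a 10 τ_r equilibration.  Trained
networks are prone to global bistability (the hidden layer can shut the
whole machine down); a hysteretic monitor therefore optionally injects the
high clamp current into any layer whose 50 ms population rate drops below
5 Hz.  Threshold 5 Hz is a modelling constant; the window and current
magnitude are package choices, since only the threshold is specified by
the phenomenon being countered.

## 6. Synthetic data

`synthetic_patterns` emulates binarized image data: disjoint blocks of
on-pixels per class (orthogonal prototypes) with independent pixel flips,
encoded to on-probabilities {10⁻⁵, 0.98} exactly as real images would be.
It reproduces the *encoding and supervision structure* of an image
benchmark, but none of its difficulty: classes are linearly separable,
within-class variability is i.i.d. noise, and there are two classes, not
ten.  Passing the end-to-end tests therefore demonstrates that the
sampler, the learning rule and the readouts compose correctly — not that
the method reaches any particular accuracy on natural images.  The IDX
reader allows the same pipeline to run on real digit data when available.

## 7. Numerical choices and degenerate inputs

- Explicit Euler–Maruyama at `dt = 0.1 ms`; synaptic currents decay by the
  exact factor `e^{−dt/τ_syn}` per step.  Noise enters as
  `(σ/C)√dt·N(0,1)` per free step.
- Refractoriness is bookkept in integer steps (`⌈τ_r/dt⌉`), so a saturated
  neuron fires at exactly `1/τ_r` and inter-spike intervals are never
  below `τ_r`.  All neurons crossing threshold in a step fire in that
  step; their PSPs land at the next step.
- The abstract sampler fires with per-step probability `1 − e^{−r(u)dt}`
  (exact for `u` held over the bin, never ≥ 1) at `dt = 20 µs`; a guard
  rejects configurations whose hazard per step is pathological (> 10³).
- `analytic_rate` integrates `erfcx(−x)` adaptively and returns 0 when the
  lower limit exceeds 25 (the rate underflows double precision there);
  `σ = 0` is rejected (the formula is undefined).
- `fit_sigmoid` rejects rates outside `(0, 1/τ_r)`; `inverse_transfer`
  rejects probabilities outside `(0, 1)`; zero-variance parameter groups
  pass through `discretize` unchanged, and a pinned-grid mode makes
  discretization an exact projection.
- All simulations are bitwise reproducible for a given seed; seeds are
  reduced mod 2³¹−1 before entering the kernels.

## 8. Known limitations

- The fitted `(β, γ)` are discretization- and protocol-dependent; they
  should be treated as simulator calibration constants, not physical
  constants of the diffusion limit.
- Current-based synapses only; no conductance-based variant, no lower
  reflecting barrier on the membrane potential, and no event-driven
  (queue-based) exact integration.
- The CD-equivalence of the learning rule holds for stationary,
  uncorrelated activity and neglects within-epoch weight drift; training
  stability therefore requires small per-spike magnitudes.
- Sampling accuracy degrades with weight magnitude (alpha-PSP overlap
  error grows with `|W|`); validation draws already use strong weights,
  but heavily trained networks can exceed them.
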