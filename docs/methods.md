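# Methods

## Model definition and conventions

The DyBM is a network of `N` binary neurons in discrete time.  All history
dependence flows through three bounded summaries, updated locally after every
presented pattern.  The package fixes the following conventions (the state
"at clock t" summarises `x[0..t-1]` and is what scores or generates `x[t]`):

* **Neural trace** `γ[j,l] = Σ_{s<t} μ_l^(t−s) x[s,j]`, recursion
  `γ ← μ_l (γ + x)`.  The most recent spike carries weight `μ_l`.
* **Synaptic trace** `α[i,j,k] = Σ_{s≤t−d} λ_k^(t−s−d) x[s,i]` with
  `d = d[i,j]`, recursion `α ← λ_k α + (queue head)`.  Only spikes that have
  completed the conduction delay contribute; the newest arrival carries
  weight 1.
* **Queue summary** `β[i,j,l] = Σ_{lag=1}^{d−1} μ_l^(d−lag) x[t−lag,i]`:
  spikes nearer the queue head (older, about to arrive) weigh more, rising
  to `μ_l` just before arrival.

Queues for all `N²` ordered pairs (self-connections included, treated like
any other synapse) are backed by one ring buffer of the last `max(d)−1`
patterns; `d[i,j] = 1` simply means an empty queue and the "arriving" value
is the current input — no special-casing anywhere.  Because the trace
recursions must reproduce their defining sums *exactly*, the unit tests
compare the stored state after random histories against literal
transcriptions of those sums (tolerance 1e−10); that oracle, not the
recursion, is the specification of record, which also guards the exponent
conventions above against transcription drift.

Energy, probability and likelihood follow the standard energy-based form:
`E_j(x_j) = −x_j a_j` with activation
`a_j = b_j + Σ u_ijk α_ijk − Σ v_ijl β_ijl − Σ v_jil γ_il`, spike probability
`σ(a_j/τ)` (computed as a logistic of the energy gap, stable to |a|/τ ≈ 1e4),
and per-step log-likelihood `Σ_j log P(x_j | past)`.  Deterministic
generation is the τ→0 limit: spike iff `P > 0.5` strictly, a tie emitting 0.

## Learning rule

Presenting `x[t]` produces the exact gradient of `log P(x[t] | past)`:
bias `x_j − ⟨X_j⟩`; LTP `(x_j − ⟨X_j⟩) α_ijk`; LTD in two components,
`(⟨X_j⟩ − x_j) β_ijl` (spikes in transit toward j) and `(⟨X_i⟩ − x_i) γ_jl`
(pre/post roles swapped).  All components are computed from the same
pre-update parameters and pre-advance state, then applied; the state advances
afterwards.  A central finite-difference test over 100 random instances
(relative error ≤ 1e−5) is the repository's main correctness oracle, and a
fixed-tiny-rate ascent test confirms every single update increases the
presented step's likelihood.

**AdaGrad.**  Each scalar keeps its own accumulator of squared gradients; the
two LTD components accumulate independently and apply sequentially.  The rate
for an update divides the base rate (η₀ = 1) by the square root of the
accumulator *including* the current gradient, except that a scalar's very
first update uses η₀ itself.  The inclusive accumulator is essential: with a
lagged accumulator (rate from past squares only) a near-zero first gradient
licenses an unbounded second step, and in practice parameters diverge within
a few periods.  With the inclusive form every step is bounded by η₀.  An
ε = 1e−12 guards the division; it is inert at these scales.

## Synthetic inputs (what the generator emulates)

All experiment inputs are regenerated from code.  Text is rendered in a
packaged 7-row × 5-column block font (letters S, C, I, E, N; "I" is mirror
symmetric, which matters for cue ambiguity in the mirrored experiments);
bitmap columns become successive 7-bit patterns, so "SCIENCE" is a periodic
sequence of 35 patterns.  The exact glyph shapes are this package's own —
any bit-level result (e.g. the period count at convergence) is defined
relative to this font, not to any other rendering of the same text.
Architectures are densely connected with conduction delays drawn i.i.d.
uniform on {1..9}; decay rates are fixed at K = L = 3 with
λ = μ = (0.25, 0.5, 0.75); parameters initialise i.i.d. Normal(0, 0.1).
One master seed spawns three named RNG streams (delays, parameter init,
sampling) so each randomness source is independently reproducible.
The generator produces noise-free periodic targets; real spike data is
neither binary-clean nor periodic, so passing these experiments demonstrates
the learning rule and memory mechanism, not robustness to biological noise.

## Training protocols and problem sizes

**Memorization.**  One training period presents one period of the target.
Every 10 periods (configurable) the live state is cloned and two periods are
generated closed-loop; convergence is a bit-exact match against the target
rotated to the phase after the last presented column.  With the defaults the
35-column target converges after ~1,200–14,000 periods depending on the seed
(seconds of wall time); the budget is 130,000 periods.

**Anomaly scoring.**  The trained model scores each pattern of a sequence by
its negative log-likelihood, advancing traces and queues but never the
parameters.  The reference demo scores "SCIENSESCIENCE" from the live
post-training state, reproducing the spike of surprise at the anomalous
glyph (and the smaller one where the second "SCIEN" unexpectedly follows
"SE").

**Dual-sequence recall.**  Odd iterations train the forward sequence, even
iterations its mirror, each iteration ending when the sequence's cue —
presented to a zeroed state, without learning — retrieves one exact period;
the run ends when both cues succeed at once.  Two design choices here are
the package's own.  First, each iteration starts from a blank dynamic state
(parameters and optimiser persist): a blank interlude between sessions is
the same idealisation as the blank pre-training history, and it stops the
gradient from being taken across meaningless sequence-switch transitions.
Without it the alternation destabilises — per-iteration period counts grow
exponentially instead of shrinking.  Second, retrieval is checked every 25
periods.  The scaled demo pair ("SCI" and its mirror, period 15, 10-column
cues) then terminates with both retrievals exact for most seeds in seconds
to minutes, with the relearning speed-up clearly visible (first iteration
~75 periods, final ~25).  Termination is seed-dependent: some seeds enter
long grinds exceeding the period budget, which the API reports as
`converged=False` rather than raising.  The full-scale pair (period 35,
25-column cues) oscillates stably for thousands of iterations and, by
extrapolation from the original experiment's ~1.8 million iterations, lies
far beyond desk scale; it is supported through `dybm demo dual --full`,
which checkpoints after every 50 iterations and resumes exactly.

## Numerical and degenerate-input choices

* Probabilities and log-likelihoods go through `expit`/`log_expit` (or their
  compiled equivalents); raw exponentials of energies are never formed.
* Ties at probability exactly 0.5 in deterministic generation emit 0.
* `sd = 0` initialisation, empty cues, aperiodic memorization targets, and
  non-binary patterns are rejected with `ValueError`s at the boundary.
* The compiled kernels (numba) duplicate the reference numpy recursions for
  the two hot loops only (training steps, closed-loop generation); the test
  suite pins the two paths together to ≤1e−12 over multi-period runs.
  Floating-point summation order differs between the paths, so agreement is
  asserted numerically, not bitwise; all shipped protocols use the kernels,
  so any given experiment is bitwise reproducible under a fixed seed.

## Known limitations

* No hidden neurons, real-valued inputs, or joint Gibbs sampling; the model
  is fully visible and conditionally factorised, as implemented.
* The dual-sequence protocol's termination is a property of the alternating
  dynamics, not guaranteed; unlucky seeds exhaust their budget.
* Anomaly scores are raw NLLs; no calibration or thresholding is provided.
* The font is a stand-in for the original rendering, so period counts and
  NLL magnitudes are comparable in order, not digit-for-digit.
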