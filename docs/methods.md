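# Methods

This note documents the models, algorithmic conventions and design choices
behind `phitau`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and where genuinely open choices were
made.

## Generative models

All three models share one forward-accumulation scheme. Every timepoint of
every channel is initialised to an independent Gaussian noise draw
(mean 0, variance 0.5), and source times are processed in increasing order;
each connection then adds `coeff * source(t)` into the target channel at
`t + lag`. Contributions landing beyond the end of the series are
discarded. Because lags are ≥ 1, a value is complete (all incoming
contributions applied) before it is ever read as a source — in particular
before it is tested against the gate threshold.

* **Nonlinear 2-channel** (`nonlinear_2ch`): self-coefficients
  a = c = −0.1 (self-inhibition), cross-coefficients b = d = 0.9, fixed lag
  l = 10. With a fixed lag the accumulation scheme is exactly the recurrence
  `X(t) = aX(t−l) + bY(t−l) + ε_X(t)` with the first `l` samples pure noise.
* **Non-Markovian 2-channel** (`non_markovian_2ch`): same coefficients, but
  each contribution's lag is drawn independently from {9, 10, 11} with
  probabilities {0.25, 0.5, 0.25}. No single fixed-lag state determines the
  next state, yet the elements still interact at a timescale of ~10.
* **Non-Markovian 3-channel** (`non_markovian_3ch`): three channels, all
  self-coefficients −0.1 and all six cross-connections 0.4, jittered lags
  as above.

Cross-connections are *gated*: the coefficient takes its configured value
only when the source channel's realised voltage exceeds the threshold (0.9),
else 0 — a caricature of reliable transmission through bursting.
Self-connections are ungated. The gate tests the realised (noisy) voltage,
as written in the recurrence.

Choices a reader should know about:

* **Initial conditions / burn-in.** The first samples are pure noise in all
  models (the accumulation form makes this automatic) and no burn-in is
  discarded by default (`burn_in` is configurable). The processes are
  stationary enough at these parameters that the first `l` samples are
  immaterial at n = 20,000.
* **Gate timing in the jittered-lag models.** The threshold is tested
  against the fully accumulated source value — source times processed in
  increasing order — so `Y(t)` is final before it gates `b·Y(t)`.
* **Divergence guard.** |voltage| > 10⁶ aborts with the run and timepoint
  named; the configured parameter regime is stable, so the guard only
  catches misconfiguration.
* **Simulation protocol.** 10 runs of 20,000 timepoints per model, seeded
  per run from a single `SeedSequence`; output is bit-identical for a given
  seed.

## Binarisation and TPM estimation

Each channel is binarised against its own median *within the run* (and
within the offset, for downsampling): strictly greater → 1, ties → 0. Ties
have measure zero for continuous data; a constant channel binarises to all
zeros with a warning. System states are indexed little-endian (channel 0 =
least significant bit) everywhere.

* **Skipping, timescale τ:** tally (state at t, per-node states at t + τ)
  over all t; exactly n − τ transitions.
* **Downsampling, timescale τ:** for every offset o ∈ {0, …, τ−1}, drop o
  samples, average consecutive bins of exactly τ samples, binarise each
  offset's coarse series against its own medians, tally transitions between
  consecutive coarse steps, and pool tallies over offsets. Each offset
  contributes ⌊(n−o)/τ⌋ − 1 transitions; the pooled total lies in
  [n − 2τ, n − τ]. (The commonly quoted total "n − τ − 1" is an O(1)
  approximation to this exact per-offset bookkeeping.) Offsets with fewer
  than two complete bins contribute nothing and are logged.

Rows never observed as a transition source are imputed at the
maximum-entropy value 0.5 per node and flagged; the imputed fraction
propagates into Φ results so downstream analyses can report it. The
state-by-state expansion assumes conditional independence of the next-state
nodes given the current state, `p(s′|s) = Π_j p_j(s)^{s′_j}(1−p_j(s))^{1−s′_j}`,
which is exact for the state-by-node estimator used here.

## Integrated information (IIT 3.0)

Computed exactly for 2–3 binary nodes from the state-by-node TPM.

* **Repertoires.** Cause: Bayesian posterior over the purview's past states
  given the mechanism's current state, maximum-entropy prior, with the
  virtual-element factorisation (each mechanism node's constraint computed
  independently, multiplied, renormalised). Effect: distribution over the
  purview's next states given the mechanism, non-mechanism inputs at
  maximum entropy; purview nodes are conditionally independent. Conditioning
  on a zero-probability mechanism state returns the uniform repertoire with
  a warning.
* **Mechanism φ.** For each direction, over all non-empty purviews: the
  minimum over mechanism/purview bipartitions of the EMD (Hamming ground
  metric on purview states) between whole and partitioned repertoires;
  φ_direction is the maximum over purviews, and φ = min(φ_cause, φ_effect).
  Partitions pair an undirected mechanism bipartition (possibly empty first
  part) with a directed purview bipartition, excluding parts that are empty
  on both sides. Partition comparisons are **unnormalised**, following the
  IIT 3.0 formulation (partition-size normalisation is an IIT 2.0 device).
* **Ties.** φ differences below 10⁻⁹ are treated as ties and broken toward
  the earliest candidate in a fixed enumeration order (subsets ascending by
  size, then lexicographically). The tolerance sits well above
  floating-point noise, so mathematically tied purviews resolve identically
  regardless of evaluation order — necessary for cross-implementation
  agreement, since exact ties are common (e.g. a purview extended by a
  reducible node).
* **System Φ.** The constellation of all irreducible concepts (φ > 10⁻¹⁰)
  is compared against the constellation under every unidirectional
  bipartition cut: connections from part A into part B are severed by
  marginalising B-nodes' inputs from A to maximum entropy. There are
  2ⁿ − 2 such cuts (2 for n = 2, 6 for n = 3). The distance is the extended
  EMD: φ values are the masses, the ground distance between concepts is the
  cause-plus-effect repertoire EMD over the union of their purviews (each
  side's missing nodes filled with its own subsystem's unconstrained
  repertoire), and surplus mass on either side pays the distance to the
  corresponding subsystem's null (unconstrained) concept. Φ is the minimum
  over cuts. All mechanisms are re-evaluated under each cut rather than
  assuming cuts cannot create concepts.
* **EMD.** All transportation problems (at most 2³ states, or a handful of
  concepts plus a null node) are solved exactly by a successive-shortest-
  path min-cost-flow routine, cross-checked in the tests against an
  independent linear-program formulation.
* **Aggregation over time.** Φ is computed per observed source state and
  aggregated as the state-frequency-weighted mean (frequencies = empirical
  occurrence among transition sources at the same τ). The per-state map is
  always retained, so any other aggregation can be recomputed. Conditioning
  uses the source state at t, not t + τ.
* **Background conditions** are never fixed: TPMs for a channel subset are
  built from that subset alone, implicitly marginalising everything else —
  the partial-observation regime.

A deliberately naive reference implementation (direct enumeration over
joint states, scipy-linprog EMD, no caching) lives in the test suite and
must agree with the optimised engine to 10⁻⁶ on random 2- and 3-node TPMs.

## Timescale sweep and peak model

The default τ grid
{1, 2, 3, 4, 5, 6, 8, 10, 13, 16, 20, 25, 32, 40, 50, 64, 90, 128, 180, 256, 360, 512}
is approximately exponential but deliberately contains non-powers of two
(10, 360, …) so integer interaction lags can be resolved exactly. Φ is
log-transformed (natural log) for analysis because it is positively skewed;
Φ = 0 records are kept in the Φ column but their log is recorded as missing
and list-wise deleted from fits, never as −∞.

Δlog(Φ) is the difference of log Φ between two conditions per matched
(subject, pair, run, method, τ) record — the log of the Φ ratio — and is
antisymmetric under swapping conditions. Unmatched records are excluded and
logged. Records enter the fit unaveraged (record-level fitting); averaging
over runs first is a caller-side choice.

The peak model regresses the response on x = log₂ τ:
linear (β₀ + β₁x) versus quadratic (β₀ + β₁x + β₂x²), both with random
intercepts for subject and subject:pair, estimated by **maximum likelihood**
(not REML — the likelihood-ratio comparison is of fixed effects).
χ² = 2(LL_quad − LL_lin) with 1 degree of freedom. The turning point is
2^(−β₁/2β₂), a local maximum iff β₂ < 0, and is called an *intermediate*
peak when it lies strictly inside the τ grid's range. Degenerate designs
degrade gracefully: a singular or non-converging variance component is
dropped (flagged in `notes`), and a single subject falls back to OLS.

## Synthetic two-condition data

`two_condition_sweep` emulates the *shape* of a two-condition multi-subject
sweep table: 13 subjects × 10 channel pairs (the scale of a small
multi-electrode study, kept modest so validation loops run quickly), a
linear-in-x baseline, shared and condition-specific subject and
subject:pair intercepts, iid noise (sd 0.15), and a planted multiplicative
Φ bump — additive in log Φ, a parabola with height 0.4 and curvature 0.02
per (log₂ τ)² peaking at τ\*. Because the planted Δ process follows the
quadratic mixed model exactly, the fitted turning point estimates τ\* with
known ground truth; curvature and noise are of the order seen in real
Δlog(Φ) fits (|β₂| ~ 10⁻²).

What these generators do **not** emulate: autocorrelated residuals along τ
(neighbouring τ values share data in real sweeps), Φ-versus-τ trends driven
by TPM estimation artefacts, heteroscedasticity across τ, or anatomical
structure among pairs. Passing the recovery tests therefore shows the
statistical stage is correct and well calibrated under its own model — not
that real recordings satisfy that model.

## Problem sizes and numerics

The validation protocol runs each generative model at 10 runs × 20,000
timepoints and sweeps the full default grid; 2-node Φ evaluates in
milliseconds per TPM, and the fully observed 3-node sweep (220 TPMs × 8
states × 7 constellations each) completes in a few minutes on one core
thanks to concept caching (concepts depend on the system state only through
the mechanism's own state) and the small exact EMD solver. Repertoire
comparisons use absolute tolerances of 10⁻¹² in tests; Φ agreement with the
brute-force reference is required at 10⁻⁶.

## Known limitations

* Systems are limited to 2–3 binary nodes; there is no complex search
  (exclusion-postulate subset search), no spatial coarse-graining or
  black-boxing, and no perturbational TPM estimation — observation only.
* Continuous-valued Φ is out of scope; simulation output is only consumed
  after binarisation.
* The AR models are generative only; no model fitting to data is provided.
* Zero-Φ records are deleted from fits rather than modelled (e.g. by a
  hurdle component); with the simulated systems such records are rare
  except far from the interaction timescale.
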