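# phitau

**At which temporal scale does integrated information peak?**

`phitau` is a research library for asking that question of continuous,
noisy, multichannel time series — the kind produced by local field
potential recordings — and of the autoregressive toy models used to
validate the approach. It implements the full analysis chain:

1. **Simulation** — threshold-gated autoregressive generators for 2- and
   3-channel systems whose elements interact with a known delay
   (`l = 10` samples by default), including a non-Markovian variant with
   probabilistically jittered lags (9/10/11 with probabilities
   0.25/0.5/0.25). These stand in for real recordings: continuous,
   stochastic, with a ground-truth interaction timescale.
2. **State coding** — per-channel median binarisation and empirical
   state-by-node transition probability matrices (TPMs) at a timescale τ,
   by either the **skipping** method (transitions between samples τ apart)
   or the **downsampling** method (bin-averaging τ samples, pooled over all
   τ starting offsets).
3. **Integrated information** — a complete IIT 3.0 implementation for 2–3
   binary nodes: cause/effect repertoires, mechanism-level irreducibility φ
   (earth mover's distance between whole and partitioned repertoires,
   maximised over purviews), and system-level Φ as the minimal extended-EMD
   constellation distance over unidirectional cuts.
4. **Timescale analysis** — τ sweeps per run/condition/channel pair, the
   two-condition contrast Δlog(Φ) = log Φ_wake − log Φ_anaesthesia, and a
   mixed-effects quadratic model in x = log₂ τ

   Δlog(Φ) ~ β₀ + β₁x + β₂x² + (1|subject) + (1|subject:pair)

   fitted by maximum likelihood, tested against the linear model with a
   likelihood-ratio χ²(1), and summarised by its turning point
   τ\* = 2^(−β₁/2β₂) — a candidate intermediate-timescale peak when β₂ < 0.

## A worked example

```python
import phitau as pt

runs = pt.simulate(pt.nonlinear_2ch(n_timepoints=6000, n_runs=3, seed=7))
df = pt.sweep(runs, "skipping", tau_grid=(1, 2, 3, 5, 8, 10, 13, 16, 25, 40, 64, 128))
print(pt.mean_phi_curve(df).round(4))
print("argmax tau:", pt.argmax_tau(df))
```

prints

```
tau
1      0.0001
2      0.0003
3      0.0002
5      0.0002
8      0.0002
10     0.1296
13     0.0003
16     0.0001
25     0.0001
40     0.0112
64     0.0001
128    0.0001
Name: phi, dtype: float64
argmax tau: 10
```

Φ is near zero at timescales where the binarised transitions carry no
cross-channel structure and rises two orders of magnitude at τ = 10 — the
lag at which the generative model's elements actually interact (with a
small echo at the harmonic τ = 40). The same recovery holds for the
downsampling method, for the jittered-lag model, and for 2-channel subsets
of the 3-channel model (partial observation).

The `examples/` directory walks through each capability: simulation,
TPM construction, a single Φ computation with its per-state values and
minimal cuts, the τ sweep, the Δlog(Φ) quadratic fit on a synthetic
two-condition dataset with a planted bump, and the end-to-end pipeline
driven by a YAML config.

## Layout

```
src/phitau/
  simulate.py   threshold-gated AR generators (2/3 channels, fixed or jittered lags)
  coding.py     median binarisation; skipping & downsampling TPMs; state-by-state expansion
  phi.py        IIT 3.0 repertoires, concepts, system Phi (2-3 binary nodes)
  _emd.py       exact EMD via a min-cost-flow transportation solver (numba)
  sweep.py      tau sweeps, Delta-log(Phi), quadratic mixed-model peak fit
  synthetic.py  two-condition generators with planted ground truth
  pipeline.py   YAML config, artifact I/O, end-to-end run
docs/methods.md the model, algorithmic conventions, and design choices
examples/       one narrative script per capability
```
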