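"""Binarise a simulated run and build TPMs with both timescale methods.

At the model's true interaction lag (tau = 10) the skipping TPM shows strong
state-dependence: the probability that a channel is "on" 10 samples later
depends on the other channel's current state (the cross-coupling).  Rows are
system states (channel 0 = least significant bit); columns are per-channel
"on" probabilities.
"""

import numpy as np

import phitau as pt

run = pt.simulate(pt.nonlinear_2ch(n_timepoints=20_000, n_runs=1, seed=42))[0]
binary = pt.binarize_median(run)
print(f"medians used for binarisation: {np.round(binary.thresholds_used, 4)}")

for tau in (1, 10):
    tpm = pt.build_tpm_skipping(binary, tau)
    print(f"\nskipping TPM at tau={tau} ({tpm.counts.sum()} transitions = n - tau):")
    for s in range(4):
        bits = f"{s & 1}{(s >> 1) & 1}"
        print(f"  state {bits}: P(on at t+tau) = {np.round(tpm.probabilities[s], 3)}"
              f"  (seen {tpm.counts[s]}x)")

tpm_d = pt.build_tpm_downsampling(run, 10)
print(f"\ndownsampling TPM at tau=10 pools {tpm_d.counts.sum()} transitions "
      f"over 10 offsets:")
print(np.round(tpm_d.probabilities, 3))
print("\nstate-by-state expansion (rows sum to 1):")
print(np.round(pt.sbn_to_sbs(tpm_d).probabilities, 3))
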