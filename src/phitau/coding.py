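"""Binarisation and empirical transition-probability-matrix construction.

Continuous channels are reduced to binary states by comparing each sample to
the channel's median within the run (strictly-greater -> 1, ties -> 0).  From
the binary states, a *state-by-node* TPM at timescale ``tau`` is estimated in
one of two ways:

* **skipping** — tally transitions between the system state at ``t`` and the
  per-node states at ``t + tau``, leaving the samples untouched; ``n - tau``
  transitions are available.
* **downsampling** — average voltages in contiguous bins of ``tau`` samples,
  once for every starting offset ``0 .. tau-1``; binarise each offset's coarse
  series against its own medians; tally transitions between consecutive
  coarse steps, pooling tallies across all offsets.

System states are indexed little-endian: row index ``sum_j s_j * 2**j`` with
channel 0 the least significant bit.  Rows never observed as a transition
source are imputed with the maximum-entropy value 0.5 per node and flagged, so
downstream consumers can report the imputed fraction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .simulate import MultiChannelSeries

logger = logging.getLogger(__name__)

__all__ = [
    "BinarySeries",
    "StateByNodeTPM",
    "StateByStateTPM",
    "binarize_median",
    "build_tpm_skipping",
    "build_tpm_downsampling",
    "sbn_to_sbs",
    "state_index",
    "state_bits",
    "STATE_INDEX_CONVENTION",
]

STATE_INDEX_CONVENTION = "little-endian (channel 0 = least significant bit)"


def state_index(bits: np.ndarray) -> np.ndarray:
    """Little-endian state index of per-channel bits, shape (channels, ...)."""
    bits = np.asarray(bits)
    weights = (1 << np.arange(bits.shape[0])).reshape((-1,) + (1,) * (bits.ndim - 1))
    return (bits * weights).sum(axis=0)


def state_bits(index: int, n_channels: int) -> tuple[int, ...]:
    """Per-channel bits of a little-endian state index."""
    return tuple((index >> j) & 1 for j in range(n_channels))


@dataclass
class BinarySeries:
    """Binary channel states, channels x timepoints, with the medians used."""

    states: np.ndarray
    thresholds_used: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("binary states must be 0/1")

    @property
    def n_channels(self) -> int:
        return self.states.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.states.shape[1]

    def subset(self, channels: tuple[int, ...]) -> "BinarySeries":
        return BinarySeries(
            self.states[list(channels), :], self.thresholds_used[list(channels)]
        )


@dataclass
class StateByNodeTPM:
    """Empirical state-by-node TPM at one timescale.

    ``probabilities[i, j]`` is the probability that channel ``j`` is "on" one
    coarse step (skipping: ``tau`` samples) after the system was observed in
    state ``i``; ``counts[i]`` is the number of transitions whose source was
    state ``i``.
    """

    probabilities: np.ndarray
    counts: np.ndarray
    tau: int
    method: str
    n_channels: int
    imputed_rows: np.ndarray = field(default=None)  # type: ignore[assignment]
    state_index_convention: str = STATE_INDEX_CONVENTION

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n_states = 2**self.n_channels
        if self.probabilities.shape != (n_states, self.n_channels):
            raise ValueError("probabilities must be 2^n x n")
        if self.probabilities.min() < 0 or self.probabilities.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.imputed_rows is None:
            self.imputed_rows = self.counts == 0
        self.imputed_rows = np.asarray(self.imputed_rows, dtype=bool)

    @property
    def n_states(self) -> int:
        return 2**self.n_channels

    @property
    def imputed_row_fraction(self) -> float:
        return float(self.imputed_rows.mean())

    @property
    def state_frequencies(self) -> np.ndarray:
        """Empirical occurrence frequency of each state among transition sources."""
        total = self.counts.sum()
        if total == 0:
            return np.full(self.n_states, 1.0 / self.n_states)
        return self.counts / total

    def to_json(self) -> str:
        return json.dumps(
            {
                "probabilities": self.probabilities.tolist(),
                "counts": self.counts.tolist(),
                "tau": int(self.tau),
                "method": self.method,
                "n_channels": int(self.n_channels),
                "state_index_convention": self.state_index_convention,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StateByNodeTPM":
        d = json.loads(text)
        return cls(
            probabilities=np.array(d["probabilities"], dtype=float),
            counts=np.array(d["counts"], dtype=np.int64),
            tau=d["tau"],
            method=d["method"],
            n_channels=d["n_channels"],
            state_index_convention=d.get("state_index_convention", STATE_INDEX_CONVENTION),
        )


@dataclass
class StateByStateTPM:
    """Row-stochastic 2^n x 2^n TPM (conditional-independence expansion)."""

    probabilities: np.ndarray
    tau: int
    method: str
    n_channels: int
    state_index_convention: str = STATE_INDEX_CONVENTION

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        n_states = 2**self.n_channels
        if self.probabilities.shape != (n_states, n_states):
            raise ValueError("probabilities must be 2^n x 2^n")
        if not np.allclose(self.probabilities.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows must sum to 1")


def binarize_median(series: MultiChannelSeries | np.ndarray) -> BinarySeries:
    """Binarise each channel against its own median within the run.

    A sample maps to 1 iff it strictly exceeds the channel median (ties -> 0).
    Constant channels degenerate to all zeros; a warning is logged because the
    resulting state space cannot be fully explored.
    """
    values = series.values if isinstance(series, MultiChannelSeries) else np.asarray(series, float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a channels x timepoints array with >= 2 timepoints")
    medians = np.median(values, axis=1)
    states = (values > medians[:, None]).astype(np.uint8)
    for ch in np.flatnonzero(np.ptp(values, axis=1) == 0):
        logger.warning("channel %d is constant; binarised to all zeros", ch)
    return BinarySeries(states=states, thresholds_used=medians)


def _tally(src_states: np.ndarray, next_bits: np.ndarray, n_channels: int):
    """Tally (source state, next per-node bit) pairs.

    src_states: (T,) little-endian indices; next_bits: (channels, T).
    Returns (on_counts: 2^n x n, counts: 2^n).
    """
    n_states = 2**n_channels
    counts = np.bincount(src_states, minlength=n_states).astype(np.int64)
    on = np.empty((n_states, n_channels), dtype=np.int64)
    for j in range(n_channels):
        on[:, j] = np.bincount(src_states, weights=next_bits[j], minlength=n_states)
    return on, counts


def _finalise(on: np.ndarray, counts: np.ndarray, tau: int, method: str, n_channels: int):
    probs = np.full_like(on, 0.5, dtype=float)
    observed = counts > 0
    probs[observed] = on[observed] / counts[observed, None]
    n_imputed = int((~observed).sum())
    if n_imputed:
        logger.debug(
            "%s TPM at tau=%d: %d/%d rows unobserved, imputed at 0.5",
            method, tau, n_imputed, len(counts),
        )
    return StateByNodeTPM(
        probabilities=probs,
        counts=counts,
        tau=tau,
        method=method,
        n_channels=n_channels,
        imputed_rows=~observed,
    )


def build_tpm_skipping(binary: BinarySeries, tau: int) -> StateByNodeTPM:
    """State-by-node TPM from transitions ``tau`` samples apart.

    Exactly ``n_timepoints - tau`` transitions are tallied.
    """
    n = binary.n_timepoints
    if not 1 <= tau < n:
        raise ValueError(f"tau must satisfy 1 <= tau < n_timepoints, got {tau}")
    idx = state_index(binary.states)
    src = idx[: n - tau]
    nxt = binary.states[:, tau:]
    on, counts = _tally(src, nxt, binary.n_channels)
    assert counts.sum() == n - tau
    return _finalise(on, counts, tau, "skipping", binary.n_channels)


def coarse_binaries(
    values: np.ndarray, tau: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Offset-wise coarse binary series for bin-averaging at scale ``tau``.

    For each offset ``o`` in ``0 .. tau-1``: drop the first ``o`` samples,
    average consecutive bins of exactly ``tau`` samples per channel (trailing
    partial bin discarded), and binarise each channel against the median of
    that offset's coarse series.  Returns (coarse_bits, medians) per offset
    that yields at least 2 complete bins.
    """
    values = np.asarray(values, dtype=float)
    n_ch, n = values.shape
    out = []
    for offset in range(tau):
        n_bins = (n - offset) // tau
        if n_bins < 2:
            logger.warning(
                "offset %d at tau=%d leaves %d complete bin(s); skipped", offset, tau, n_bins
            )
            continue
        binned = values[:, offset : offset + n_bins * tau].reshape(n_ch, n_bins, tau).mean(axis=2)
        medians = np.median(binned, axis=1)
        out.append(((binned > medians[:, None]).astype(np.uint8), medians))
    return out


def build_tpm_downsampling(
    series: MultiChannelSeries | np.ndarray, tau: int
) -> StateByNodeTPM:
    """State-by-node TPM from bin-averaged coarse series, pooled over offsets.

    Each offset contributes ``floor((n - offset)/tau) - 1`` transitions; the
    pooled total lies in ``[n - 2*tau, n - tau]``.
    """
    values = series.values if isinstance(series, MultiChannelSeries) else np.asarray(series, float)
    n_ch, n = values.shape
    if not 1 <= tau <= n // 2:
        raise ValueError(f"tau must satisfy 1 <= tau <= n_timepoints/2, got {tau}")
    n_states = 2**n_ch
    on = np.zeros((n_states, n_ch), dtype=np.int64)
    counts = np.zeros(n_states, dtype=np.int64)
    for bits, _medians in coarse_binaries(values, tau):
        idx = state_index(bits)
        o, c = _tally(idx[:-1], bits[:, 1:], n_ch)
        on += o
        counts += c
    return _finalise(on, counts, tau, "downsampling", n_ch)


def sbn_to_sbs(tpm: StateByNodeTPM) -> StateByStateTPM:
    """Expand a state-by-node TPM to state-by-state via conditional independence.

    ``p(s' | s) = prod_j [ p_j(s) if s'_j = 1 else 1 - p_j(s) ]``.
    """
    n = tpm.n_channels
    n_states = tpm.n_states
    probs = np.ones((n_states, n_states), dtype=float)
    for j in range(n):
        bit_j = (np.arange(n_states) >> j) & 1  # s'_j for each next state
        p_j = tpm.probabilities[:, j][:, None]
        probs *= np.where(bit_j[None, :] == 1, p_j, 1.0 - p_j)
    return StateByStateTPM(
        probabilities=probs, tau=tpm.tau, method=tpm.method, n_channels=n
    )
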