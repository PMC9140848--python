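"""Threshold-gated autoregressive generators for continuous multichannel series.

The generators emulate mesoscopic neural voltage recordings (noisy, continuous,
multichannel): each channel is driven by Gaussian noise plus delayed self- and
cross-channel terms, with cross-connections gated so that they transmit only
when the source channel's voltage exceeds a burst threshold.  Three presets are
provided:

* :func:`nonlinear_2ch` — two channels, fixed interaction lag ``l`` (Markovian
  at lag ``l``),
* :func:`non_markovian_2ch` — two channels with each delayed contribution's lag
  jittered over {9, 10, 11} (so no single fixed-lag state determines the next),
* :func:`non_markovian_3ch` — three fully cross-connected channels with
  jittered lags.

All models are simulated in the same forward-accumulation form: every
timepoint is initialised to its noise draw, and, processing source times in
increasing order, each connection adds ``coeff * value`` into the target
channel at ``t + lag``.  For a fixed lag this is exactly the textbook
recurrence ``X(t) = a X(t-l) + b Y(t-l) + eps(t)`` with the first ``l`` points
being pure noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

__all__ = [
    "LagSpec",
    "Connection",
    "ARModelConfig",
    "MultiChannelSeries",
    "simulate",
    "nonlinear_2ch",
    "non_markovian_2ch",
    "non_markovian_3ch",
    "SimulationDivergedError",
]


class SimulationDivergedError(RuntimeError):
    """Raised when a simulated voltage exceeds the blow-up guard."""


@dataclass(frozen=True)
class LagSpec:
    """Discrete distribution over integer lags (in samples).

    A fixed lag ``l`` is the degenerate distribution ``LagSpec.fixed(l)``.
    """

    values: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.probs):
            raise ValueError("values and probs must have equal length")
        if any(v < 1 for v in self.values):
            raise ValueError("all lags must be >= 1")
        if any(p < 0 for p in self.probs):
            raise ValueError("lag probabilities must be >= 0")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("lag probabilities must sum to 1")

    @classmethod
    def fixed(cls, lag: int) -> "LagSpec":
        return cls((int(lag),), (1.0,))

    @property
    def max_lag(self) -> int:
        return max(self.values)

    @property
    def is_fixed(self) -> bool:
        return len(self.values) == 1


#: Jittered lag used by the non-Markovian models: 9, 10 or 11 samples with
#: probabilities 0.25, 0.5, 0.25.
JITTERED_LAG = LagSpec((9, 10, 11), (0.25, 0.5, 0.25))


@dataclass(frozen=True)
class Connection:
    """One delayed additive term ``coeff * source(t) -> target(t + lag)``.

    ``gated`` connections contribute only when the source voltage exceeds the
    model threshold (self-connections are ungated in all presets).
    """

    source: int
    target: int
    coeff: float
    gated: bool


@dataclass(frozen=True)
class ARModelConfig:
    n_channels: int
    connections: tuple[Connection, ...]
    threshold: float
    lag_spec: LagSpec
    noise_variance: float = 0.5
    n_timepoints: int = 20_000
    n_runs: int = 10
    seed: int = 0
    burn_in: int = 0
    guard: float = 1e6
    condition_label: str = "simulated"

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")
        if self.n_timepoints <= self.lag_spec.max_lag:
            raise ValueError("n_timepoints must exceed the maximum lag")
        if self.burn_in < 0 or self.burn_in >= self.n_timepoints:
            raise ValueError("burn_in must lie in [0, n_timepoints)")
        for c in self.connections:
            if not (0 <= c.source < self.n_channels and 0 <= c.target < self.n_channels):
                raise ValueError(f"connection {c} references a missing channel")


@dataclass
class MultiChannelSeries:
    """Continuous voltages, channels x timepoints, for one run."""

    values: np.ndarray
    run_id: int = 0
    condition_label: str = ""
    seed_used: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be channels x timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series values must be finite")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def subset(self, channels: tuple[int, ...]) -> "MultiChannelSeries":
        """A view of a subset of channels (partial observation)."""
        return MultiChannelSeries(
            self.values[list(channels), :],
            run_id=self.run_id,
            condition_label=self.condition_label,
            seed_used=self.seed_used,
        )


def _bidirectional(n: int, self_coeff: float, cross_coeff: float) -> tuple[Connection, ...]:
    conns: list[Connection] = []
    for ch in range(n):
        conns.append(Connection(ch, ch, self_coeff, gated=False))
    for src in range(n):
        for dst in range(n):
            if src != dst:
                conns.append(Connection(src, dst, cross_coeff, gated=True))
    return tuple(conns)


def nonlinear_2ch(
    *,
    self_coeff: float = -0.1,
    cross_coeff: float = 0.9,
    threshold: float = 0.9,
    lag: int = 10,
    noise_variance: float = 0.5,
    n_timepoints: int = 20_000,
    n_runs: int = 10,
    seed: int = 0,
) -> ARModelConfig:
    """Two bidirectionally coupled channels with a fixed interaction lag.

    Defaults are the nonlinear model's study conditions: self-inhibition
    ``a = c = -0.1``, gated cross-coupling ``b = d = 0.9`` at threshold 0.9,
    lag 10, noise variance 0.5, 10 runs of 20,000 timepoints.
    """
    return ARModelConfig(
        n_channels=2,
        connections=_bidirectional(2, self_coeff, cross_coeff),
        threshold=threshold,
        lag_spec=LagSpec.fixed(lag),
        noise_variance=noise_variance,
        n_timepoints=n_timepoints,
        n_runs=n_runs,
        seed=seed,
        condition_label="nonlinear-2ch",
    )


def non_markovian_2ch(
    *,
    self_coeff: float = -0.1,
    cross_coeff: float = 0.9,
    threshold: float = 0.9,
    lag_spec: LagSpec = JITTERED_LAG,
    noise_variance: float = 0.5,
    n_timepoints: int = 20_000,
    n_runs: int = 10,
    seed: int = 0,
) -> ARModelConfig:
    """Two coupled channels whose delayed contributions have jittered lags."""
    return ARModelConfig(
        n_channels=2,
        connections=_bidirectional(2, self_coeff, cross_coeff),
        threshold=threshold,
        lag_spec=lag_spec,
        noise_variance=noise_variance,
        n_timepoints=n_timepoints,
        n_runs=n_runs,
        seed=seed,
        condition_label="non-markovian-2ch",
    )


def non_markovian_3ch(
    *,
    self_coeff: float = -0.1,
    cross_coeff: float = 0.4,
    threshold: float = 0.9,
    lag_spec: LagSpec = JITTERED_LAG,
    noise_variance: float = 0.5,
    n_timepoints: int = 20_000,
    n_runs: int = 10,
    seed: int = 0,
) -> ARModelConfig:
    """Three fully cross-connected channels with jittered lags."""
    return ARModelConfig(
        n_channels=3,
        connections=_bidirectional(3, self_coeff, cross_coeff),
        threshold=threshold,
        lag_spec=lag_spec,
        noise_variance=noise_variance,
        n_timepoints=n_timepoints,
        n_runs=n_runs,
        seed=seed,
        condition_label="non-markovian-3ch",
    )


@njit(cache=True)
def _accumulate(values, src, dst, coeff, gated, threshold, lag_of, lag_values, guard):
    # values: (C, T) pre-filled with noise draws; lag_of: (T, K) index into
    # lag_values per (source time, connection).  Source times are processed in
    # increasing order so every value is final (all contributions received)
    # before it is read as a source or tested against the gate threshold.
    n_ch, n_t = values.shape
    n_conn = src.shape[0]
    for t in range(n_t):
        for c in range(n_ch):
            if abs(values[c, t]) > guard:
                return t
        for k in range(n_conn):
            v = values[src[k], t]
            if gated[k] and not (v > threshold):
                continue
            tgt_t = t + lag_values[lag_of[t, k]]
            if tgt_t < n_t:
                values[dst[k], tgt_t] += coeff[k] * v
    return -1


def simulate(config: ARModelConfig) -> list[MultiChannelSeries]:
    """Simulate ``config.n_runs`` independent runs of the configured model.

    Returns one :class:`MultiChannelSeries` per run, each of length
    ``config.n_timepoints`` minus the configured burn-in.  Runs are seeded
    from ``config.seed`` via :class:`numpy.random.SeedSequence` and are
    bit-identical across repeated calls.
    """
    conns = config.connections
    src = np.array([c.source for c in conns], dtype=np.int64)
    dst = np.array([c.target for c in conns], dtype=np.int64)
    coeff = np.array([c.coeff for c in conns], dtype=np.float64)
    gated = np.array([c.gated for c in conns], dtype=np.bool_)
    lag_values = np.array(config.lag_spec.values, dtype=np.int64)
    lag_probs = np.array(config.lag_spec.probs, dtype=np.float64)

    out: list[MultiChannelSeries] = []
    children = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    for run_id, child in enumerate(children):
        rng = np.random.default_rng(child)
        values = rng.normal(
            0.0, np.sqrt(config.noise_variance), size=(config.n_channels, config.n_timepoints)
        )
        if config.lag_spec.is_fixed:
            lag_of = np.zeros((config.n_timepoints, len(conns)), dtype=np.int64)
        else:
            lag_of = rng.choice(
                len(lag_values), size=(config.n_timepoints, len(conns)), p=lag_probs
            ).astype(np.int64)
        bad_t = _accumulate(
            values, src, dst, coeff, gated, config.threshold, lag_of, lag_values, config.guard
        )
        if bad_t >= 0:
            raise SimulationDivergedError(
                f"voltage exceeded guard {config.guard:g} in run {run_id} at timepoint {bad_t}"
            )
        out.append(
            MultiChannelSeries(
                values[:, config.burn_in :],
                run_id=run_id,
                condition_label=config.condition_label,
                seed_used=config.seed,
            )
        )
    return out
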