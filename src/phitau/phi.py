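"""IIT 3.0 integrated information (Φ) for binary systems of 2–3 nodes.

Implements the full cause–effect-structure algorithm of integrated
information theory 3.0 for small binary systems described by an empirical
transition probability matrix:

* cause/effect *repertoires* of a mechanism over a purview, with the
  virtual-element factorisation (each mechanism node's constraint computed
  independently, multiplied, renormalised) and maximum-entropy treatment of
  unconstrained variables;
* mechanism-level irreducibility φ: for each direction, the maximum over
  purviews of the minimum over mechanism/purview bipartitions of the earth
  mover's distance (Hamming ground metric) between the whole and partitioned
  repertoires;
* system-level Φ: the constellation of all irreducible concepts is compared,
  via the extended (constellation-level) EMD, against the constellation of
  the system under every unidirectional bipartition cut (connections from one
  part to the other replaced by maximum-entropy noise); Φ is the minimum over
  cuts.

Partition comparisons are unnormalised, cuts are the ``2**n - 2``
unidirectional bipartitions, and ties are broken toward the earliest
candidate in a fixed enumeration order (subsets ascending by size then
lexicographically), so results are deterministic.

Aggregation over time: :func:`phi_timeseries` computes Φ for every system
state observed as a transition source and reports the state-frequency
weighted mean alongside the per-state values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from ._emd import emd, hamming_matrix, transport_cost
from .coding import BinarySeries, StateByNodeTPM, StateByStateTPM

logger = logging.getLogger(__name__)

__all__ = [
    "CAUSE",
    "EFFECT",
    "Repertoire",
    "Concept",
    "Constellation",
    "PhiResult",
    "Subsystem",
    "SystemPhi",
    "repertoire",
    "mechanism_concept",
    "system_phi_state",
    "phi_timeseries",
    "unidirectional_cuts",
    "node_subsets",
]

CAUSE = "cause"
EFFECT = "effect"

#: Concepts with φ at or below this tolerance are treated as reducible.
PHI_EPS = 1e-10

#: φ differences below this are treated as ties during the purview search,
#: which are then broken toward the earliest purview in enumeration order
#: (smallest, then lexicographic).  Must sit well above floating-point noise
#: so that mathematically tied purviews resolve identically regardless of
#: evaluation order.
TIE_TOL = 1e-9


def node_subsets(n: int, *, nonempty: bool = True):
    """Subsets of range(n), ordered by size then lexicographically."""
    out = [] if nonempty else [()]
    for size in range(1, n + 1):
        out.extend(combinations(range(n), size))
    return out


def unidirectional_cuts(n: int):
    """All unidirectional bipartition cuts (severed_from, severed_to).

    One cut per nonempty proper subset A: connections from A into the
    complement are severed (replaced by maximum-entropy noise).
    """
    cuts = []
    for part in node_subsets(n):
        if len(part) == n:
            continue
        rest = tuple(sorted(set(range(n)) - set(part)))
        cuts.append((part, rest))
    return cuts


@dataclass(frozen=True)
class Repertoire:
    """A probability distribution over the states of a purview.

    The distribution is little-endian over the purview: bit ``k`` of the
    state index is the state of node ``purview[k]``.
    """

    purview: tuple[int, ...]
    direction: str
    distribution: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "distribution", np.asarray(self.distribution, dtype=float)
        )
        if len(self.distribution) != 2 ** len(self.purview):
            raise ValueError("distribution length must be 2^|purview|")
        if abs(self.distribution.sum() - 1.0) > 1e-9:
            raise ValueError("distribution must sum to 1")


@dataclass(frozen=True)
class Concept:
    """A mechanism with its maximally irreducible cause/effect repertoires."""

    mechanism: tuple[int, ...]
    mechanism_state: tuple[int, ...]
    cause_repertoire: Repertoire
    effect_repertoire: Repertoire
    small_phi: float
    phi_cause: float
    phi_effect: float


@dataclass
class Constellation:
    """All irreducible concepts of a system in a given state."""

    concepts: list[Concept]
    system_state: tuple[int, ...]

    def __post_init__(self) -> None:
        mechs = [c.mechanism for c in self.concepts]
        if len(set(mechs)) != len(mechs):
            raise ValueError("duplicate mechanisms in constellation")

    @property
    def sum_phi(self) -> float:
        return float(sum(c.small_phi for c in self.concepts))

    def __len__(self) -> int:
        return len(self.concepts)


@dataclass
class PhiResult:
    """System-level Φ per observed state plus the frequency-weighted mean."""

    phi_per_state: dict[str, float]
    state_frequencies: dict[str, float]
    phi_aggregate: float
    minimal_cut: dict[str, tuple | None]
    imputed_row_fraction: float
    tau: int | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        if self.phi_per_state:
            lo = min(self.phi_per_state.values())
            hi = max(self.phi_per_state.values())
            if not (lo - 1e-9 <= self.phi_aggregate <= hi + 1e-9):
                raise ValueError("aggregate must lie within per-state range")

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "phi_per_state": self.phi_per_state,
                "state_frequencies": self.state_frequencies,
                "phi_aggregate": self.phi_aggregate,
                "minimal_cut": {
                    k: None if v is None else [list(v[0]), list(v[1])]
                    for k, v in self.minimal_cut.items()
                },
                "imputed_row_fraction": self.imputed_row_fraction,
                "tau": self.tau,
                "method": self.method,
            }
        )


def state_string(index: int, n: int) -> str:
    """Little-endian state string, channel 0 first (state 2 of 2 -> '01')."""
    return "".join(str((index >> j) & 1) for j in range(n))


def _as_node_probs(tpm) -> np.ndarray:
    """Coerce any accepted TPM form to a (2^n, n) state-by-node array."""
    if isinstance(tpm, StateByNodeTPM):
        return tpm.probabilities
    if isinstance(tpm, StateByStateTPM):
        sbs = tpm.probabilities
        n = tpm.n_channels
        node_probs = np.empty((2**n, n))
        nxt = np.arange(2**n)
        for j in range(n):
            node_probs[:, j] = sbs[:, ((nxt >> j) & 1) == 1].sum(axis=1)
        return node_probs
    arr = np.asarray(tpm, dtype=float)
    if arr.ndim == 2 and arr.shape[0] == arr.shape[1] and arr.shape[0] > arr.shape[1]:
        raise ValueError("ambiguous TPM array; pass a StateByNodeTPM or StateByStateTPM")
    if arr.ndim != 2 or arr.shape[0] != 2 ** arr.shape[1]:
        raise ValueError("expected a 2^n x n state-by-node array")
    return arr


class Subsystem:
    """A (possibly cut) binary system: per-node conditional distributions.

    ``node_probs[i, j]`` is p(node j on at the next step | current state i).
    A cut ``(A, B)`` severs connections from A into B: each node in B has its
    inputs from A marginalised to maximum entropy.
    """

    def __init__(self, node_probs: np.ndarray, cut: tuple | None = None):
        node_probs = np.asarray(node_probs, dtype=float)
        self.n = node_probs.shape[1]
        self.cut = cut
        shape = (2,) * self.n
        self._p = []
        for j in range(self.n):
            pj = node_probs[:, j].reshape(shape, order="F")
            if cut is not None and j in cut[1]:
                severed = tuple(sorted(cut[0]))
                pj = np.broadcast_to(
                    pj.mean(axis=severed, keepdims=True), shape
                ).copy()
            self._p.append(pj)
        self._cause_factor: dict = {}
        self._effect_scalar: dict = {}
        self._rep_cache: dict = {}
        self._partition_cache: dict = {}
        self._concepts: dict = {}
        self._null = None

    # -- repertoires ------------------------------------------------------

    def _factor_cause(self, node: int, node_state: int, purview: tuple[int, ...]):
        key = (node, node_state, purview)
        f = self._cause_factor.get(key)
        if f is None:
            L = self._p[node] if node_state == 1 else 1.0 - self._p[node]
            other = tuple(ax for ax in range(self.n) if ax not in purview)
            f = L.sum(axis=other) if other else L
            f = np.asarray(f).reshape(-1, order="F")
            self._cause_factor[key] = f
        return f

    def cause_repertoire(
        self,
        mechanism: tuple[int, ...],
        mechanism_state: tuple[int, ...],
        purview: tuple[int, ...],
    ) -> np.ndarray:
        """Posterior over the purview's past states given the mechanism state.

        Maximum-entropy prior over past states; each mechanism node's
        constraint is computed independently (virtual elements), multiplied,
        and renormalised.  An unconstrained (empty) mechanism gives the
        uniform distribution.
        """
        size = 2 ** len(purview)
        if not mechanism:
            return np.full(size, 1.0 / size)
        r = np.ones(size)
        for m, s in zip(mechanism, mechanism_state):
            r = r * self._factor_cause(m, s, purview)
        tot = r.sum()
        if tot <= 0.0:
            logger.warning(
                "conditioning on zero-probability mechanism state %s=%s; "
                "returning uniform cause repertoire",
                mechanism,
                mechanism_state,
            )
            return np.full(size, 1.0 / size)
        return r / tot

    def _scalar_effect(
        self, node: int, mechanism: tuple[int, ...], mechanism_state: tuple[int, ...]
    ) -> float:
        key = (node, mechanism, mechanism_state)
        e = self._effect_scalar.get(key)
        if e is None:
            idx = [slice(None)] * self.n
            for m, s in zip(mechanism, mechanism_state):
                idx[m] = s
            e = float(np.mean(self._p[node][tuple(idx)]))
            self._effect_scalar[key] = e
        return e

    def effect_repertoire(
        self,
        mechanism: tuple[int, ...],
        mechanism_state: tuple[int, ...],
        purview: tuple[int, ...],
    ) -> np.ndarray:
        """Distribution over the purview's next states given the mechanism.

        Non-mechanism current nodes are set to maximum entropy; purview nodes
        are conditionally independent given the current state, so the
        repertoire is the product of per-node Bernoulli factors.
        """
        vec = np.ones(1)
        for j in purview:
            e = self._scalar_effect(j, mechanism, mechanism_state)
            # prepend node j as the next-higher bit (little-endian purview)
            vec = (np.array([1.0 - e, e])[:, None] * vec[None, :]).ravel()
        return vec

    def repertoire(self, direction, mechanism, mechanism_state, purview) -> np.ndarray:
        key = (direction, mechanism, mechanism_state, purview)
        rep = self._rep_cache.get(key)
        if rep is not None:
            return rep
        if direction == CAUSE:
            rep = self.cause_repertoire(mechanism, mechanism_state, purview)
        elif direction == EFFECT:
            rep = self.effect_repertoire(mechanism, mechanism_state, purview)
        else:
            raise ValueError(f"direction must be 'cause' or 'effect', got {direction!r}")
        self._rep_cache[key] = rep
        return rep

    def unconstrained_repertoire(self, direction, purview) -> np.ndarray:
        return self.repertoire(direction, (), (), purview)

    # -- mechanism-level φ -------------------------------------------------

    def _partitions(self, mechanism: tuple[int, ...], purview: tuple[int, ...]):
        key = (mechanism, purview)
        parts = self._partition_cache.get(key)
        if parts is None:
            parts = list(self._mip_partitions(mechanism, purview))
            self._partition_cache[key] = parts
        return parts

    @staticmethod
    def _mip_partitions(mechanism: tuple[int, ...], purview: tuple[int, ...]):
        """Bipartitions ((M1,P1),(M2,P2)) of mechanism and purview.

        Mechanism bipartitions are undirected (the last mechanism node is
        pinned to part 2), purview bipartitions directed; parts with both an
        empty mechanism and an empty purview are excluded.
        """
        m_rest = mechanism[:-1]
        m_subsets = [()]
        for size in range(1, len(m_rest) + 1):
            m_subsets.extend(combinations(m_rest, size))
        p_subsets = [()]
        for size in range(1, len(purview) + 1):
            p_subsets.extend(combinations(purview, size))
        for m1 in m_subsets:
            m2 = tuple(x for x in mechanism if x not in m1)
            for p1 in p_subsets:
                p2 = tuple(x for x in purview if x not in p1)
                if (m1 or p1) and (m2 or p2):
                    yield (m1, p1), (m2, p2)

    def _partitioned_repertoire(
        self, direction, parts, system_state: tuple[int, ...], purview: tuple[int, ...]
    ) -> np.ndarray:
        shape = (2,) * len(purview)
        out = np.ones(shape)
        pos = {node: k for k, node in enumerate(purview)}
        for mech_i, purv_i in parts:
            if not purv_i:
                continue
            state_i = tuple(system_state[m] for m in mech_i)
            r = self.repertoire(direction, mech_i, state_i, purv_i)
            axes_shape = [1] * len(purview)
            for node in purv_i:
                axes_shape[pos[node]] = 2
            out = out * r.reshape(axes_shape, order="F")
        return out.reshape(-1, order="F")

    def find_mice(
        self, direction: str, mechanism: tuple[int, ...], system_state: tuple[int, ...]
    ) -> tuple[float, Repertoire]:
        """Maximally irreducible cause/effect of a mechanism.

        Returns (φ_direction, repertoire at the maximising purview).  φ for a
        purview is the minimum over partitions of the EMD between whole and
        partitioned repertoires; the maximum over purviews is returned.  Ties
        keep the earliest purview/partition in enumeration order.
        """
        mech_state = tuple(system_state[m] for m in mechanism)
        best_phi = -1.0
        best_rep = None
        for purview in node_subsets(self.n):
            whole = self.repertoire(direction, mechanism, mech_state, purview)
            D = hamming_matrix(len(purview))
            min_phi = np.inf
            for parts in self._partitions(mechanism, purview):
                part_rep = self._partitioned_repertoire(
                    direction, parts, system_state, purview
                )
                phi_p = emd(whole, part_rep, D)
                if phi_p < min_phi:
                    min_phi = phi_p
                if min_phi < 1e-12:
                    break
            if min_phi > best_phi + TIE_TOL:
                best_phi = min_phi
                best_rep = Repertoire(purview, direction, whole)
        return float(best_phi), best_rep

    def concept(
        self, mechanism: tuple[int, ...], system_state: tuple[int, ...]
    ) -> Concept | None:
        """The concept of a mechanism, or None if reducible (φ ≈ 0).

        Concepts depend on the system state only through the mechanism's own
        state, so they are cached per (mechanism, mechanism state).
        """
        if not mechanism:
            raise ValueError("mechanism must be non-empty")
        mech_state = tuple(system_state[m] for m in mechanism)
        key = (mechanism, mech_state)
        if key in self._concepts:
            return self._concepts[key]
        phi_c, rep_c = self.find_mice(CAUSE, mechanism, system_state)
        concept = None
        if phi_c > PHI_EPS:
            phi_e, rep_e = self.find_mice(EFFECT, mechanism, system_state)
            if phi_e > PHI_EPS:
                concept = Concept(
                    mechanism=mechanism,
                    mechanism_state=mech_state,
                    cause_repertoire=rep_c,
                    effect_repertoire=rep_e,
                    small_phi=min(phi_c, phi_e),
                    phi_cause=phi_c,
                    phi_effect=phi_e,
                )
        self._concepts[key] = concept
        return concept

    def constellation(self, system_state: tuple[int, ...]) -> Constellation:
        concepts = []
        for mechanism in node_subsets(self.n):
            c = self.concept(mechanism, system_state)
            if c is not None:
                concepts.append(c)
        return Constellation(concepts=concepts, system_state=tuple(system_state))

    # -- null concept ------------------------------------------------------

    @property
    def null_concept(self) -> Concept:
        """The unconstrained concept: uniform cause, unconstrained effect."""
        if self._null is None:
            full = tuple(range(self.n))
            self._null = Concept(
                mechanism=(),
                mechanism_state=(),
                cause_repertoire=Repertoire(
                    full, CAUSE, self.unconstrained_repertoire(CAUSE, full)
                ),
                effect_repertoire=Repertoire(
                    full, EFFECT, self.unconstrained_repertoire(EFFECT, full)
                ),
                small_phi=0.0,
                phi_cause=0.0,
                phi_effect=0.0,
            )
        return self._null


def _expand(rep: Repertoire, sub: Subsystem, union: tuple[int, ...]) -> np.ndarray:
    """Expand a repertoire over a larger purview.

    Missing nodes are filled with the subsystem's unconstrained repertoire
    for the same direction (uniform for cause).
    """
    if rep.purview == union:
        return rep.distribution
    shape = [1] * len(union)
    pos = {node: k for k, node in enumerate(union)}
    rep_shape = list(shape)
    for node in rep.purview:
        rep_shape[pos[node]] = 2
    out = rep.distribution.reshape(rep_shape, order="F")
    extra = tuple(node for node in union if node not in rep.purview)
    if extra:
        uc = sub.unconstrained_repertoire(rep.direction, extra)
        uc_shape = [1] * len(union)
        for node in extra:
            uc_shape[pos[node]] = 2
        out = out * uc.reshape(uc_shape, order="F")
    return np.broadcast_to(out, (2,) * len(union)).reshape(-1, order="F")


def concept_distance(c1: Concept, sub1: Subsystem, c2: Concept, sub2: Subsystem) -> float:
    """Cause-plus-effect EMD between two concepts.

    Each direction's repertoires are expanded over the union of the two
    purviews (using each concept's own subsystem for the unconstrained
    filler) and compared with the Hamming-ground EMD.
    """
    total = 0.0
    for r1, r2 in (
        (c1.cause_repertoire, c2.cause_repertoire),
        (c1.effect_repertoire, c2.effect_repertoire),
    ):
        union = tuple(sorted(set(r1.purview) | set(r2.purview)))
        D = hamming_matrix(len(union))
        total += emd(_expand(r1, sub1, union), _expand(r2, sub2, union), D)
    return total


class SystemPhi:
    """Φ computation for one TPM, caching concepts across states and cuts."""

    def __init__(self, tpm):
        node_probs = _as_node_probs(tpm)
        self.n = node_probs.shape[1]
        if not 2 <= self.n <= 3:
            raise ValueError(
                f"system-level Phi supports 2-3 nodes, got {self.n}"
            )
        self.uncut = Subsystem(node_probs)
        self.cuts = unidirectional_cuts(self.n)
        self.cut_subs = {cut: Subsystem(node_probs, cut) for cut in self.cuts}
        self._pair_cache: dict = {}
        self._null_cache: dict = {}

    def _dist(self, c1, sub1, key1, c2, sub2, key2) -> float:
        key = (key1, c1.mechanism, c1.mechanism_state, key2, c2.mechanism, c2.mechanism_state)
        d = self._pair_cache.get(key)
        if d is None:
            d = concept_distance(c1, sub1, c2, sub2)
            self._pair_cache[key] = d
        return d

    def _dist_to_null(self, c: Concept, sub: Subsystem, key) -> float:
        k = (key, c.mechanism, c.mechanism_state)
        d = self._null_cache.get(k)
        if d is None:
            d = concept_distance(c, sub, sub.null_concept, sub)
            self._null_cache[k] = d
        return d

    def constellation_emd(
        self, C1: Constellation, C2: Constellation, cut
    ) -> float:
        """Extended EMD between uncut and cut constellations.

        φ values are the masses; the ground distance between concepts is the
        cause-plus-effect repertoire EMD; surplus mass on either side pays the
        distance to the corresponding subsystem's null concept.
        """
        sub2 = self.cut_subs[cut]
        s1 = C1.sum_phi
        s2 = C2.sum_phi
        if s1 <= PHI_EPS and s2 <= PHI_EPS:
            return 0.0
        supply = [c.small_phi for c in C1.concepts] + [max(0.0, s2 - s1)]
        demand = [c.small_phi for c in C2.concepts] + [max(0.0, s1 - s2)]
        n1, n2 = len(C1.concepts), len(C2.concepts)
        costs = np.zeros((n1 + 1, n2 + 1))
        for i, c1 in enumerate(C1.concepts):
            for j, c2 in enumerate(C2.concepts):
                costs[i, j] = self._dist(c1, self.uncut, "uncut", c2, sub2, cut)
            costs[i, n2] = self._dist_to_null(c1, self.uncut, "uncut")
        for j, c2 in enumerate(C2.concepts):
            costs[n1, j] = self._dist_to_null(c2, sub2, cut)
        return transport_cost(np.array(supply), np.array(demand), costs)

    def phi_state(self, system_state) -> tuple[float, tuple | None, Constellation]:
        """Φ of one system state: minimum constellation distance over cuts."""
        system_state = tuple(int(s) for s in system_state)
        C1 = self.uncut.constellation(system_state)
        if not C1.concepts:
            logger.warning("no irreducible concepts in state %s; Phi = 0", system_state)
            return 0.0, None, C1
        best = np.inf
        best_cut = None
        for cut in self.cuts:
            C2 = self.cut_subs[cut].constellation(system_state)
            d = self.constellation_emd(C1, C2, cut)
            if d < best:
                best = d
                best_cut = cut
        return float(max(best, 0.0)), best_cut, C1


# -- module-level operations ------------------------------------------------


def repertoire(tpm, mechanism, mechanism_state, purview, direction) -> Repertoire:
    """Cause or effect repertoire of a mechanism state over a purview."""
    sub = Subsystem(_as_node_probs(tpm))
    dist = sub.repertoire(
        direction, tuple(mechanism), tuple(mechanism_state), tuple(purview)
    )
    return Repertoire(tuple(purview), direction, dist)


def mechanism_concept(tpm, mechanism, system_state) -> Concept:
    """The concept of a mechanism in a system state (φ = 0 if reducible)."""
    sub = Subsystem(_as_node_probs(tpm))
    mechanism = tuple(mechanism)
    system_state = tuple(int(s) for s in system_state)
    c = sub.concept(mechanism, system_state)
    if c is not None:
        return c
    mech_state = tuple(system_state[m] for m in mechanism)
    phi_c, rep_c = sub.find_mice(CAUSE, mechanism, system_state)
    phi_e, rep_e = sub.find_mice(EFFECT, mechanism, system_state)
    return Concept(
        mechanism=mechanism,
        mechanism_state=mech_state,
        cause_repertoire=rep_c,
        effect_repertoire=rep_e,
        small_phi=min(phi_c, phi_e),
        phi_cause=phi_c,
        phi_effect=phi_e,
    )


def system_phi_state(tpm, system_state):
    """System-level Φ for one state: (phi, minimal_cut, constellation)."""
    return SystemPhi(tpm).phi_state(system_state)


def phi_timeseries(tpm: StateByNodeTPM, binary: BinarySeries | None = None) -> PhiResult:
    """Φ for every observed source state plus the frequency-weighted mean.

    State frequencies are the empirical occurrence frequencies among
    transition source states (the TPM's row counts).  ``binary`` is accepted
    for interface symmetry but the TPM's own counts are authoritative.
    """
    n = tpm.n_channels
    engine = SystemPhi(tpm)
    freqs = tpm.state_frequencies
    phi_per_state: dict[str, float] = {}
    min_cut: dict[str, tuple | None] = {}
    state_freq: dict[str, float] = {}
    agg = 0.0
    if tpm.imputed_rows.all():
        logger.warning("all TPM rows imputed; Phi = 0")
    for s in range(2**n):
        if tpm.counts[s] == 0:
            continue
        key = state_string(s, n)
        phi, cut, _ = engine.phi_state(state_bits_of(s, n))
        phi_per_state[key] = phi
        min_cut[key] = cut
        state_freq[key] = float(freqs[s])
        agg += freqs[s] * phi
    return PhiResult(
        phi_per_state=phi_per_state,
        state_frequencies=state_freq,
        phi_aggregate=float(agg),
        minimal_cut=min_cut,
        imputed_row_fraction=tpm.imputed_row_fraction,
        tau=tpm.tau,
        method=tpm.method,
    )


def state_bits_of(index: int, n: int) -> tuple[int, ...]:
    return tuple((index >> j) & 1 for j in range(n))
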