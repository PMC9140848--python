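"""Independent brute-force IIT 3.0 reference implementation (test oracle).

Deliberately written as a separate code path from the package: everything is
computed by direct enumeration over full joint states of a state-by-state
TPM, earth mover's distances are solved with scipy.optimize.linprog, and no
caching or vectorised layout tricks are used.  Slow, but transparent — used
only to cross-validate the package's Φ engine on small random systems.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.optimize import linprog

PHI_EPS = 1e-10
TIE_TOL = 1e-9  # purview ties broken toward the earliest purview


def bits_of(index, n):
    return tuple((index >> j) & 1 for j in range(n))


def subsets(nodes, nonempty=True):
    out = [] if nonempty else [()]
    for size in range(1, len(nodes) + 1):
        out.extend(combinations(nodes, size))
    return out


def lp_emd(p, q, D):
    """Exact EMD via the transportation linear program."""
    m, n = len(p), len(q)
    c = np.asarray(D, dtype=float).reshape(-1)
    A_eq = []
    b_eq = []
    for i in range(m):
        row = np.zeros((m, n))
        row[i, :] = 1.0
        A_eq.append(row.reshape(-1))
        b_eq.append(p[i])
    for j in range(n):
        row = np.zeros((m, n))
        row[:, j] = 1.0
        A_eq.append(row.reshape(-1))
        b_eq.append(q[j])
    res = linprog(c, A_eq=np.array(A_eq), b_eq=np.array(b_eq), bounds=(0, None), method="highs")
    assert res.success, res.message
    return float(res.fun)


def hamming(a, b):
    return bin(a ^ b).count("1")


def hamming_D(n_bits):
    size = 2**n_bits
    return np.array([[hamming(i, j) for j in range(size)] for i in range(size)], float)


class OracleSystem:
    """IIT 3.0 quantities computed from a state-by-state TPM by enumeration."""

    def __init__(self, sbs, n):
        self.T = np.asarray(sbs, dtype=float)
        self.n = n
        self.states = list(range(2**n))

    # node conditional p(node j on next | past full state u), with an
    # optional unidirectional cut (from_part -> to_part severed to noise)
    def node_on(self, j, u, cut=None):
        if cut is not None and j in cut[1]:
            frm = cut[0]
            vals = []
            for w in self.states:
                # w agrees with u outside the severed sources
                if all(
                    bits_of(w, self.n)[k] == bits_of(u, self.n)[k]
                    for k in range(self.n)
                    if k not in frm
                ):
                    vals.append(sum(self.T[w, v] for v in self.states if (v >> j) & 1))
            return float(np.mean(vals))
        return float(sum(self.T[u, v] for v in self.states if (v >> j) & 1))

    def cause_rep(self, mechanism, mech_state, purview, cut=None):
        size = 2 ** len(purview)
        if not mechanism:
            return np.full(size, 1.0 / size)
        rep = np.ones(size)
        for m, s in zip(mechanism, mech_state):
            factor = np.zeros(size)
            for pi in range(size):
                pbits = bits_of(pi, len(purview))
                for u in self.states:
                    ubits = bits_of(u, self.n)
                    if all(ubits[purview[k]] == pbits[k] for k in range(len(purview))):
                        p_on = self.node_on(m, u, cut)
                        factor[pi] += p_on if s == 1 else 1.0 - p_on
            rep = rep * factor
        tot = rep.sum()
        if tot <= 0:
            return np.full(size, 1.0 / size)
        return rep / tot

    def effect_rep(self, mechanism, mech_state, purview, cut=None):
        size = 2 ** len(purview)
        rep = np.ones(size)
        for k, j in enumerate(purview):
            vals = []
            for u in self.states:
                ubits = bits_of(u, self.n)
                if all(ubits[m] == s for m, s in zip(mechanism, mech_state)):
                    vals.append(self.node_on(j, u, cut))
            e = float(np.mean(vals))
            for pi in range(size):
                rep[pi] *= e if bits_of(pi, len(purview))[k] == 1 else 1.0 - e
        return rep

    def rep(self, direction, mechanism, mech_state, purview, cut=None):
        if direction == "cause":
            return self.cause_rep(mechanism, mech_state, purview, cut)
        return self.effect_rep(mechanism, mech_state, purview, cut)

    @staticmethod
    def partitions(mechanism, purview):
        m_rest = mechanism[:-1]
        for m1 in subsets(m_rest, nonempty=False):
            m2 = tuple(x for x in mechanism if x not in m1)
            for p1 in subsets(purview, nonempty=False):
                p2 = tuple(x for x in purview if x not in p1)
                if (m1 or p1) and (m2 or p2):
                    yield (m1, p1), (m2, p2)

    def partitioned_rep(self, direction, parts, state_bits, purview, cut=None):
        size = 2 ** len(purview)
        rep = np.ones(size)
        for mech_i, purv_i in parts:
            if not purv_i:
                continue
            ms = tuple(state_bits[m] for m in mech_i)
            sub = self.rep(direction, mech_i, ms, purv_i, cut)
            for pi in range(size):
                pbits = bits_of(pi, len(purview))
                sub_idx = 0
                for b, node in enumerate(purv_i):
                    sub_idx |= pbits[purview.index(node)] << b
                rep[pi] *= sub[sub_idx]
        return rep

    def mice(self, direction, mechanism, state_bits, cut=None):
        ms = tuple(state_bits[m] for m in mechanism)
        best_phi, best_purview, best_rep = -1.0, None, None
        for purview in subsets(tuple(range(self.n))):
            whole = self.rep(direction, mechanism, ms, purview, cut)
            D = hamming_D(len(purview))
            phi_min = np.inf
            for parts in self.partitions(mechanism, purview):
                part = self.partitioned_rep(direction, parts, state_bits, purview, cut)
                phi_min = min(phi_min, lp_emd(whole, part, D))
            if phi_min > best_phi + TIE_TOL:
                best_phi, best_purview, best_rep = phi_min, purview, whole
        return best_phi, best_purview, best_rep

    def concept(self, mechanism, state_bits, cut=None):
        phi_c, pv_c, rep_c = self.mice("cause", mechanism, state_bits, cut)
        phi_e, pv_e, rep_e = self.mice("effect", mechanism, state_bits, cut)
        return {
            "mechanism": mechanism,
            "phi": min(phi_c, phi_e),
            "cause": (pv_c, rep_c),
            "effect": (pv_e, rep_e),
        }

    def constellation(self, state_bits, cut=None):
        return [
            c
            for mech in subsets(tuple(range(self.n)))
            if (c := self.concept(mech, state_bits, cut))["phi"] > PHI_EPS
        ]

    def expand(self, direction, purview, rep, union, cut=None):
        """Expand a repertoire over a purview union, max-entropy filler."""
        extra = tuple(x for x in union if x not in purview)
        out = np.zeros(2 ** len(union))
        if extra:
            filler = self.rep(direction, (), (), extra, cut)
        else:
            filler = np.ones(1)
        for ui in range(len(out)):
            ubits = bits_of(ui, len(union))
            p_idx = 0
            for b, node in enumerate(purview):
                p_idx |= ubits[union.index(node)] << b
            e_idx = 0
            for b, node in enumerate(extra):
                e_idx |= ubits[union.index(node)] << b
            out[ui] = rep[p_idx] * filler[e_idx]
        return out

    def concept_distance(self, c1, cut1, c2, cut2):
        total = 0.0
        for direction in ("cause", "effect"):
            pv1, rep1 = c1[direction]
            pv2, rep2 = c2[direction]
            union = tuple(sorted(set(pv1) | set(pv2)))
            e1 = self.expand(direction, pv1, rep1, union, cut1)
            e2 = self.expand(direction, pv2, rep2, union, cut2)
            total += lp_emd(e1, e2, hamming_D(len(union)))
        return total

    def null_concept(self, cut=None):
        full = tuple(range(self.n))
        return {
            "mechanism": (),
            "phi": 0.0,
            "cause": (full, self.rep("cause", (), (), full, cut)),
            "effect": (full, self.rep("effect", (), (), full, cut)),
        }

    def constellation_distance(self, C1, C2, cut):
        s1 = sum(c["phi"] for c in C1)
        s2 = sum(c["phi"] for c in C2)
        if s1 <= PHI_EPS and s2 <= PHI_EPS:
            return 0.0
        null1 = self.null_concept(None)
        null2 = self.null_concept(cut)
        supply = [c["phi"] for c in C1] + [max(0.0, s2 - s1)]
        demand = [c["phi"] for c in C2] + [max(0.0, s1 - s2)]
        D = np.zeros((len(C1) + 1, len(C2) + 1))
        for i, c1 in enumerate(C1):
            for j, c2 in enumerate(C2):
                D[i, j] = self.concept_distance(c1, None, c2, cut)
            D[i, len(C2)] = self.concept_distance(c1, None, null1, None)
        for j, c2 in enumerate(C2):
            D[len(C1), j] = self.concept_distance(c2, cut, null2, cut)
        return lp_emd(np.array(supply), np.array(demand), D)

    def big_phi(self, state_bits):
        C1 = self.constellation(state_bits)
        if not C1:
            return 0.0, None
        best, best_cut = np.inf, None
        for part in subsets(tuple(range(self.n))):
            if len(part) == self.n:
                continue
            rest = tuple(sorted(set(range(self.n)) - set(part)))
            cut = (part, rest)
            C2 = self.constellation(state_bits, cut)
            d = self.constellation_distance(C1, C2, cut)
            if d < best:
                best, best_cut = d, cut
        return max(best, 0.0), best_cut
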