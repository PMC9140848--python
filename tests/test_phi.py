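"""Φ engine tests: repertoire identities, zero-Φ systems, invariances, oracle."""

import numpy as np
import pytest

import phitau as pt
from phitau.phi import CAUSE, EFFECT, SystemPhi, state_string, unidirectional_cuts

from conftest import sbs_from_sbn
from oracle_iit3 import OracleSystem, bits_of


def node_tpm(probabilities):
    p = np.asarray(probabilities, dtype=float)
    return pt.StateByNodeTPM(
        probabilities=p,
        counts=np.ones(p.shape[0], dtype=int),
        tau=1,
        method="skipping",
        n_channels=p.shape[1],
    )


# deterministic 2-node copy system: each node takes the other's previous state
COPY = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)


class TestRepertoires:
    def test_empty_mechanism_cause_is_uniform(self):
        rep = pt.repertoire(node_tpm(COPY), (), (), (0, 1), CAUSE)
        np.testing.assert_allclose(rep.distribution, 0.25)

    def test_copy_system_cause_is_point_mass(self):
        # A=1 now implies B=1 in the past (B's state is copied into A)
        rep = pt.repertoire(node_tpm(COPY), (0,), (1,), (1,), CAUSE)
        np.testing.assert_allclose(rep.distribution, [0.0, 1.0], atol=1e-12)

    def test_fully_conditioned_effect_is_the_tpm_row(self, rng):
        p = rng.uniform(0.1, 0.9, size=(4, 2))
        tpm = node_tpm(p)
        sbs = pt.sbn_to_sbs(tpm)
        for state in range(4):
            bits = bits_of(state, 2)
            rep = pt.repertoire(tpm, (0, 1), bits, (0, 1), EFFECT)
            np.testing.assert_allclose(rep.distribution, sbs.probabilities[state], atol=1e-12)

    def test_state_by_state_input_equals_state_by_node_input(self, rng):
        p = rng.uniform(0.1, 0.9, size=(4, 2))
        tpm = node_tpm(p)
        sbs = pt.sbn_to_sbs(tpm)
        for direction in (CAUSE, EFFECT):
            a = pt.repertoire(tpm, (0,), (1,), (0, 1), direction)
            b = pt.repertoire(sbs, (0,), (1,), (0, 1), direction)
            np.testing.assert_allclose(a.distribution, b.distribution, atol=1e-12)

    def test_zero_probability_conditioning_warns_and_is_uniform(self, caplog):
        # node 0 is always on next step; conditioning on node0=0 now is fine,
        # but its cause repertoire asks for pasts producing node0=0: none.
        p = np.array([[1.0, 0.5], [1.0, 0.5], [1.0, 0.5], [1.0, 0.5]])
        with caplog.at_level("WARNING"):
            rep = pt.repertoire(node_tpm(p), (0,), (0,), (0, 1), CAUSE)
        np.testing.assert_allclose(rep.distribution, 0.25)
        assert any("zero-probability" in r.message for r in caplog.records)


class TestZeroPhiSystems:
    def test_factorisable_tpm_has_zero_system_phi(self, rng):
        # each node depends only on its own previous state: single nodes may
        # still constrain their own past (irreducible self-loop concepts),
        # but composite mechanisms factorise and every system cut is free
        f0, f1 = rng.uniform(0.1, 0.9, 2), rng.uniform(0.1, 0.9, 2)
        p = np.array([[f0[s & 1], f1[(s >> 1) & 1]] for s in range(4)])
        tpm = node_tpm(p)
        for state in range(4):
            bits = bits_of(state, 2)
            joint = pt.mechanism_concept(tpm, (0, 1), bits)
            assert joint.small_phi == pytest.approx(0.0, abs=1e-9)
            phi, cut, _ = pt.system_phi_state(tpm, bits)
            assert phi == pytest.approx(0.0, abs=1e-9)

    def test_constraint_free_nodes_have_no_concepts_at_all(self, rng):
        # constant per-node rows: nothing constrains anything
        a, b = rng.uniform(0.2, 0.8, 2)
        p = np.tile([a, b], (4, 1))
        tpm = node_tpm(p)
        for mech in [(0,), (1,), (0, 1)]:
            assert pt.mechanism_concept(tpm, mech, (0, 0)).small_phi == pytest.approx(
                0.0, abs=1e-9
            )
        phi, _, constellation = pt.system_phi_state(tpm, (0, 0))
        assert phi == 0.0
        assert len(constellation) == 0

    def test_unidirectional_coupling_has_zero_phi(self, rng):
        # A drives B; A is pure noise: severing A->B costs nothing overall
        g = rng.uniform(0.1, 0.9, 2)
        p = np.array([[0.5, g[s & 1]] for s in range(4)])
        for state in range(4):
            phi, _, _ = pt.system_phi_state(node_tpm(p), bits_of(state, 2))
            assert phi == pytest.approx(0.0, abs=1e-9)

    def test_maximum_entropy_tpm_has_zero_phi(self):
        p = np.full((4, 2), 0.5)
        phi, cut, constellation = pt.system_phi_state(node_tpm(p), (0, 0))
        assert phi == 0.0
        assert len(constellation) == 0


class TestInvariances:
    def test_phi_invariant_under_node_relabelling(self, rng):
        p = rng.uniform(0.05, 0.95, size=(4, 2))
        # swap the two channels: permute rows (bit swap) and columns
        row_perm = [0, 2, 1, 3]
        p_swapped = p[row_perm][:, ::-1]
        for state in range(4):
            bits = bits_of(state, 2)
            phi_a, _, _ = pt.system_phi_state(node_tpm(p), bits)
            phi_b, _, _ = pt.system_phi_state(node_tpm(p_swapped), bits[::-1])
            assert phi_a == pytest.approx(phi_b, abs=1e-9)

    def test_small_phi_bounds(self, rng):
        p = rng.uniform(0.0, 1.0, size=(8, 3))
        tpm = node_tpm(p)
        for mech in [(0,), (1, 2), (0, 1, 2)]:
            c = pt.mechanism_concept(tpm, mech, (1, 0, 1))
            assert c.small_phi >= 0.0
            assert c.small_phi <= 3.0  # max Hamming EMD on <= 3-bit purviews

    def test_cut_enumeration_counts(self):
        assert len(unidirectional_cuts(2)) == 2
        assert len(unidirectional_cuts(3)) == 6


class TestOracleAgreement:
    """Spot checks against the brute-force reference; the acceptance suite
    runs the full multi-TPM comparison."""

    def test_random_two_node_tpms(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            p = rng.uniform(0.05, 0.95, size=(4, 2))
            oracle = OracleSystem(sbs_from_sbn(p), 2)
            engine = SystemPhi(p)
            for s in range(4):
                bits = bits_of(s, 2)
                phi_o, _ = oracle.big_phi(bits)
                phi_p, _, _ = engine.phi_state(bits)
                assert phi_p == pytest.approx(phi_o, abs=1e-6)

    def test_random_three_node_tpm(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.1, 0.9, size=(8, 3))
        oracle = OracleSystem(sbs_from_sbn(p), 3)
        engine = SystemPhi(p)
        phi_o, _ = oracle.big_phi((0, 1, 1))
        phi_p, _, _ = engine.phi_state((0, 1, 1))
        assert phi_p == pytest.approx(phi_o, abs=1e-6)


class TestPhiTimeseries:
    def test_single_state_series_aggregate_is_that_state(self):
        p = np.array([[0.3, 0.7], [0.2, 0.6], [0.8, 0.4], [0.6, 0.1]])
        counts = np.array([17, 0, 0, 0])
        tpm = pt.StateByNodeTPM(
            probabilities=p, counts=counts, tau=1, method="skipping", n_channels=2
        )
        res = pt.phi_timeseries(tpm)
        assert list(res.phi_per_state) == ["00"]
        assert res.phi_aggregate == pytest.approx(res.phi_per_state["00"])
        assert res.state_frequencies["00"] == 1.0

    def test_aggregate_is_frequency_weighted_and_nonnegative(self, rng):
        p = rng.uniform(0.1, 0.9, size=(4, 2))
        counts = np.array([10, 30, 40, 20])
        tpm = pt.StateByNodeTPM(
            probabilities=p, counts=counts, tau=2, method="skipping", n_channels=2
        )
        res = pt.phi_timeseries(tpm)
        manual = sum(
            res.state_frequencies[s] * res.phi_per_state[s] for s in res.phi_per_state
        )
        assert res.phi_aggregate == pytest.approx(manual)
        assert res.phi_aggregate >= 0.0
        assert res.tau == 2 and res.method == "skipping"

    def test_state_string_convention(self):
        assert state_string(1, 2) == "10"  # channel 0 on, channel 1 off
        assert state_string(2, 2) == "01"
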