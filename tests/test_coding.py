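"""Binarisation and TPM-construction tests, with hand-enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phitau as pt
from phitau.coding import coarse_binaries, state_index


class TestBinarizeMedian:
    def test_simple_split(self):
        b = pt.binarize_median(np.array([[1.0, 2.0, 3.0, 4.0]]))
        np.testing.assert_array_equal(b.states, [[0, 0, 1, 1]])
        assert b.thresholds_used[0] == 2.5

    def test_constant_channel_is_all_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            b = pt.binarize_median(np.array([[5.0, 5.0, 5.0, 5.0]]))
        np.testing.assert_array_equal(b.states, [[0, 0, 0, 0]])
        assert any("constant" in r.message for r in caplog.records)

    def test_even_length_continuous_channel_splits_in_half(self, rng):
        values = rng.normal(size=(3, 2000))
        b = pt.binarize_median(values)
        # no ties almost surely: exactly half the samples exceed the median
        np.testing.assert_array_equal(b.states.sum(axis=1), [1000, 1000, 1000])


class TestSkippingTPM:
    def test_hand_enumerated_transitions(self):
        # states: (0,0),(1,0),(0,1),(1,1),(0,0),(1,0) -> indices 0,1,2,3,0,1
        binary = pt.BinarySeries(
            states=np.array([[0, 1, 0, 1, 0, 1], [0, 0, 1, 1, 0, 0]]),
            thresholds_used=np.zeros(2),
        )
        tpm = pt.build_tpm_skipping(binary, tau=1)
        np.testing.assert_array_equal(tpm.counts, [2, 1, 1, 1])
        # row 0 -> (1,0) twice; row 1 -> (0,1); row 2 -> (1,1); row 3 -> (0,0)
        np.testing.assert_allclose(
            tpm.probabilities, [[1, 0], [0, 1], [1, 1], [0, 0]]
        )
        assert not tpm.imputed_rows.any()

    def test_single_visited_state_imputes_the_rest(self):
        binary = pt.BinarySeries(states=np.zeros((2, 50), dtype=int), thresholds_used=np.zeros(2))
        tpm = pt.build_tpm_skipping(binary, tau=3)
        np.testing.assert_allclose(tpm.probabilities[0], [0, 0])
        np.testing.assert_allclose(tpm.probabilities[1:], 0.5)
        np.testing.assert_array_equal(tpm.imputed_rows, [False, True, True, True])
        assert tpm.imputed_row_fraction == 0.75

    @settings(deadline=None, max_examples=25)
    @given(
        n=st.integers(min_value=20, max_value=400),
        tau=st.integers(min_value=1, max_value=19),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_transition_count_is_n_minus_tau(self, n, tau, seed):
        r = np.random.default_rng(seed)
        binary = pt.binarize_median(r.normal(size=(2, n)))
        tpm = pt.build_tpm_skipping(binary, tau)
        assert tpm.counts.sum() == n - tau

    def test_tau_out_of_range_raises(self):
        binary = pt.BinarySeries(states=np.zeros((1, 10), dtype=int), thresholds_used=np.zeros(1))
        with pytest.raises(ValueError):
            pt.build_tpm_skipping(binary, 10)

    def test_channel_reversal_permutes_rows_and_columns(self, rng):
        values = rng.normal(size=(2, 300))
        tpm = pt.build_tpm_skipping(pt.binarize_median(values), 5)
        tpm_rev = pt.build_tpm_skipping(pt.binarize_median(values[::-1]), 5)
        # reversing 2 channels swaps bit 0 and bit 1: rows 1<->2, columns swap
        row_perm = [0, 2, 1, 3]
        np.testing.assert_allclose(
            tpm_rev.probabilities, tpm.probabilities[row_perm][:, ::-1]
        )
        np.testing.assert_array_equal(tpm_rev.counts, tpm.counts[row_perm])


class TestDownsamplingTPM:
    def test_hand_binned_offsets(self):
        values = np.array([[1.0, 3.0, 2.0, 8.0, 5.0, 7.0, 4.0, 6.0]])
        offsets = coarse_binaries(values, tau=2)
        assert len(offsets) == 2
        bits0, med0 = offsets[0]
        # offset 0 bins: (1,3),(2,8),(5,7),(4,6) -> means 2,5,6,5; median 5
        assert med0[0] == 5.0
        np.testing.assert_array_equal(bits0, [[0, 0, 1, 0]])
        bits1, med1 = offsets[1]
        # offset 1 bins: (3,2),(8,5),(7,4) -> means 2.5, 6.5, 5.5; median 5.5
        assert med1[0] == 5.5
        np.testing.assert_array_equal(bits1, [[0, 1, 0]])

    def test_tau_1_equals_skipping_tau_1(self, rng):
        values = rng.normal(size=(2, 201))
        down = pt.build_tpm_downsampling(values, 1)
        skip = pt.build_tpm_skipping(pt.binarize_median(values), 1)
        np.testing.assert_allclose(down.probabilities, skip.probabilities)
        np.testing.assert_array_equal(down.counts, skip.counts)

    @settings(deadline=None, max_examples=25)
    @given(
        n=st.integers(min_value=40, max_value=400),
        tau=st.integers(min_value=1, max_value=20),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_pooled_transition_count_bounds(self, n, tau, seed):
        r = np.random.default_rng(seed)
        tpm = pt.build_tpm_downsampling(r.normal(size=(2, n)), tau)
        expected = sum((n - o) // tau - 1 for o in range(tau))
        assert tpm.counts.sum() == expected
        assert n - 2 * tau <= expected <= n - tau

    def test_short_offsets_are_skipped_with_warning(self, caplog):
        # n = 7, tau = 3: offset 2 leaves 1 complete bin -> skipped
        values = np.arange(7.0)[None, :]
        with caplog.at_level("WARNING"):
            offsets = coarse_binaries(values, 3)
        assert len(offsets) == 2
        assert any("skipped" in r.message for r in caplog.records)


class TestStateByState:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ((1.0, 0.0), [0, 1, 0, 0]),  # deterministic -> one-hot on state (1,0)
            ((0.5, 0.5), [0.25, 0.25, 0.25, 0.25]),
            ((0.3, 0.8), [0.7 * 0.2, 0.3 * 0.2, 0.7 * 0.8, 0.3 * 0.8]),
        ],
    )
    def test_row_expansion(self, row, expected):
        tpm = pt.StateByNodeTPM(
            probabilities=np.tile(row, (4, 1)),
            counts=np.ones(4, dtype=int),
            tau=1,
            method="skipping",
            n_channels=2,
        )
        sbs = pt.sbn_to_sbs(tpm)
        np.testing.assert_allclose(sbs.probabilities[0], expected)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(min_value=0, max_value=2**16), n=st.integers(2, 3))
    def test_rows_sum_to_one(self, seed, n):
        r = np.random.default_rng(seed)
        tpm = pt.StateByNodeTPM(
            probabilities=r.uniform(size=(2**n, n)),
            counts=np.ones(2**n, dtype=int),
            tau=1,
            method="skipping",
            n_channels=n,
        )
        sbs = pt.sbn_to_sbs(tpm)
        np.testing.assert_allclose(sbs.probabilities.sum(axis=1), 1.0, atol=1e-12)


def test_state_index_is_little_endian():
    bits = np.array([[1], [0], [1]])  # channels 0,1,2
    assert state_index(bits)[0] == 1 + 4


def test_tpm_json_roundtrip(rng):
    tpm = pt.build_tpm_skipping(pt.binarize_median(rng.normal(size=(2, 100))), 4)
    back = pt.StateByNodeTPM.from_json(tpm.to_json())
    np.testing.assert_allclose(back.probabilities, tpm.probabilities)
    np.testing.assert_array_equal(back.counts, tpm.counts)
    assert (back.tau, back.method, back.n_channels) == (4, "skipping", 2)
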