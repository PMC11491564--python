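import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgredund import (
    BinnedChannels,
    BinningConfig,
    ContractError,
    MultichannelRecord,
    UndefinedValueError,
    bin_record,
    channel_redundancy,
    conditional_entropy,
    entropy,
    joint_entropy,
    mutual_information,
    nmi,
    nmi_matrix,
    pcc,
    redundancy_report,
    set_redundancy,
)
from oracles import (
    brute_channel_redundancy,
    brute_conditional_entropy,
    brute_entropy,
    brute_nmi,
    brute_set_redundancy,
)


def binned(*columns, base=2.0):
    """Wrap integer columns directly as BinnedChannels."""
    arr = np.column_stack([np.asarray(c, dtype=np.int64) for c in columns])
    names = tuple(chr(ord("A") + i) for i in range(arr.shape[1]))
    return BinnedChannels(names, arr, BinningConfig(log_base=base))


class TestBinning:
    def test_bin_edges_half_open_anchored_at_zero(self):
        rec = MultichannelRecord(("A",), np.array([[-0.3], [0.0], [0.49], [0.5]]))
        out = bin_record(rec, BinningConfig(bin_width_mv=0.5))
        np.testing.assert_array_equal(out.bins[:, 0], [-1, 0, 0, 1])

    def test_constant_channel_single_bin(self):
        rec = MultichannelRecord(("A",), np.full((6, 1), 0.2))
        out = bin_record(rec)
        assert len(np.unique(out.bins)) == 1

    def test_halving_width_doubles_bins_on_ramp(self):
        ramp = np.linspace(0.0, 1.0, 1000, endpoint=False)[:, None]
        rec = MultichannelRecord(("A",), ramp)
        coarse = bin_record(rec, BinningConfig(bin_width_mv=0.5))
        fine = bin_record(rec, BinningConfig(bin_width_mv=0.25))
        # brute-force count of occupied bins under each width
        expect_coarse = len({math.floor(v / 0.5) for v in ramp[:, 0]})
        expect_fine = len({math.floor(v / 0.25) for v in ramp[:, 0]})
        assert len(np.unique(coarse.bins)) == expect_coarse == 2
        assert len(np.unique(fine.bins)) == expect_fine == 4

    def test_non_finite_sample_rejected_with_location(self):
        data = np.zeros((4, 2))
        data[2, 1] = np.nan
        rec = MultichannelRecord(("A", "B"), data)
        with pytest.raises(ContractError, match="sample 2.*'B'"):
            bin_record(rec)

    def test_anchor_shifts_edges(self):
        rec = MultichannelRecord(("A",), np.array([[0.0], [0.2], [0.3]]))
        out = bin_record(rec, BinningConfig(bin_width_mv=0.5, anchor=0.25))
        np.testing.assert_array_equal(out.bins[:, 0], [-1, -1, 0])

    @given(st.floats(-5, 5, allow_nan=False), st.floats(0.05, 2.0))
    @settings(deadline=None, max_examples=50)
    def test_bin_index_matches_floor_definition(self, value, width):
        rec = MultichannelRecord(("A",), np.array([[value], [value]]))
        out = bin_record(rec, BinningConfig(bin_width_mv=width))
        assert out.bins[0, 0] == math.floor(value / width)


class TestEntropy:
    def test_constant_channel_zero(self):
        assert entropy(binned([3] * 10), 0) == 0.0

    def test_fair_coin_one_bit(self):
        assert entropy(binned([0, 1] * 8), 0) == pytest.approx(1.0)

    def test_counts_4211_example(self):
        col = [0] * 4 + [1] * 2 + [2] + [3]
        assert entropy(binned(col), 0) == pytest.approx(1.75)

    def test_matches_brute_force_on_random_column(self, rng):
        col = rng.integers(-3, 4, size=200)
        assert entropy(binned(col), 0) == pytest.approx(brute_entropy(col))

    def test_log_base_e_units(self):
        h = entropy(binned([0, 1] * 8, base=math.e), 0)
        assert h == pytest.approx(math.log(2))


class TestJointEntropy:
    def test_singleton_subset_reduces_to_entropy(self, tiny_binned):
        for i in range(3):
            assert joint_entropy(tiny_binned, [i]) == pytest.approx(entropy(tiny_binned, i))

    def test_duplicated_channel_adds_nothing(self):
        col = [0, 1, 2, 0, 1, 1]
        ch = binned(col, col)
        assert joint_entropy(ch, [0, 1]) == pytest.approx(entropy(ch, 0))

    def test_independent_fair_coins_two_bits(self):
        ch = binned([0, 0, 1, 1], [0, 1, 0, 1])
        assert joint_entropy(ch, [0, 1]) == pytest.approx(2.0)

    def test_permutation_invariant(self, tiny_binned):
        for perm in itertools.permutations(range(3)):
            assert joint_entropy(tiny_binned, list(perm)) == pytest.approx(
                joint_entropy(tiny_binned, [0, 1, 2])
            )

    def test_empty_subset_rejected(self, tiny_binned):
        with pytest.raises(ContractError, match="non-empty"):
            joint_entropy(tiny_binned, [])

    def test_duplicate_indices_rejected(self, tiny_binned):
        with pytest.raises(ContractError, match="duplicate"):
            joint_entropy(tiny_binned, [0, 0])

    def test_matches_brute_force_on_all_subsets(self, tiny_binned):
        cols = [tiny_binned.bins[:, k].tolist() for k in range(3)]
        for size in (1, 2, 3):
            for subset in itertools.combinations(range(3), size):
                assert joint_entropy(tiny_binned, list(subset)) == pytest.approx(
                    brute_entropy(*[cols[k] for k in subset])
                )

    def test_large_bin_values_fall_back_safely(self):
        # spread bins so the mixed-radix pack would overflow int64
        col_a = [0, 2**40, 0, 2**40]
        col_b = [-(2**40), 0, 0, -(2**40)]
        ch = binned(col_a, col_b)
        assert joint_entropy(ch, [0, 1]) == pytest.approx(brute_entropy(col_a, col_b))


class TestMutualInformation:
    def test_identical_channels_give_marginal_entropy(self):
        col = [0, 1, 2, 0, 1, 1]
        ch = binned(col, col)
        assert mutual_information(ch, 0, 1) == pytest.approx(entropy(ch, 0))

    def test_bijective_relabeling_invariance(self):
        col = [0, 1, 2, 0, 1, 1]
        relabeled = [10 * c + 7 for c in col]
        ch = binned(col, relabeled)
        assert mutual_information(ch, 0, 1) == pytest.approx(entropy(ch, 0))

    def test_independent_fair_coins_zero(self):
        ch = binned([0, 0, 1, 1], [0, 1, 0, 1])
        assert mutual_information(ch, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_self_information_is_entropy(self, tiny_binned):
        assert mutual_information(tiny_binned, 1, 1) == pytest.approx(entropy(tiny_binned, 1))

    def test_invalid_index_rejected(self, tiny_binned):
        with pytest.raises(ContractError):
            mutual_information(tiny_binned, 0, 5)

    def test_bounded_by_min_marginal_entropy(self, rng):
        for _ in range(10):
            a = rng.integers(0, 4, 60)
            b = rng.integers(0, 4, 60)
            ch = binned(a, b)
            mi = mutual_information(ch, 0, 1)
            assert -1e-12 <= mi <= min(entropy(ch, 0), entropy(ch, 1)) + 1e-12


class TestNmi:
    def test_identical_channels_one(self):
        col = [0, 1, 2, 0, 1, 1]
        assert nmi(binned(col, col), 0, 1) == pytest.approx(1.0)

    def test_independent_channels_near_zero_large_n(self, rng):
        a = rng.integers(0, 4, 200_000)
        b = rng.integers(0, 4, 200_000)
        assert nmi(binned(a, b), 0, 1) == pytest.approx(0.0, abs=0.02)

    def test_symmetric(self, rng):
        a = rng.integers(0, 3, 100)
        b = rng.integers(0, 3, 100)
        ch = binned(a, b)
        assert nmi(ch, 0, 1) == pytest.approx(nmi(ch, 1, 0))

    def test_matches_brute_force(self, tiny_binned):
        cols = [tiny_binned.bins[:, k].tolist() for k in range(3)]
        for i, j in itertools.combinations(range(3), 2):
            assert nmi(tiny_binned, i, j) == pytest.approx(brute_nmi(cols[i], cols[j]))

    def test_both_constant_undefined(self):
        ch = binned([5] * 6, [2] * 6)
        with pytest.raises(UndefinedValueError):
            nmi(ch, 0, 1)

    def test_log_base_invariant(self, rng):
        a = rng.integers(0, 4, 100)
        b = (a + rng.integers(0, 2, 100)).tolist()
        assert nmi(binned(a, b, base=2.0), 0, 1) == pytest.approx(
            nmi(binned(a, b, base=math.e), 0, 1), abs=1e-9
        )


class TestNmiMatrix:
    def test_duplicated_channels_all_ones(self):
        col = [0, 1, 0, 2, 1]
        np.testing.assert_allclose(nmi_matrix(binned(col, col)), 1.0)

    def test_diagonal_one_and_symmetric(self, tiny_binned):
        mat = nmi_matrix(tiny_binned)
        np.testing.assert_allclose(np.diag(mat), 1.0)
        np.testing.assert_allclose(mat, mat.T)

    def test_matches_pairwise_nmi(self, tiny_binned):
        mat = nmi_matrix(tiny_binned)
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert mat[i, j] == pytest.approx(nmi(tiny_binned, i, j))

    def test_constant_channel_error_names_pair(self):
        ch = binned([0, 1, 0, 1], [3, 3, 3, 3])
        with pytest.raises(UndefinedValueError, match=r"B, B"):
            nmi_matrix(ch)


class TestChannelRedundancy:
    def test_duplicated_channel_fully_redundant(self, rng):
        col = rng.integers(0, 4, 50)
        other = rng.integers(0, 4, 50)
        ch = binned(col, other, col)
        assert channel_redundancy(ch, 0) == pytest.approx(1.0)

    def test_independent_channel_near_zero_large_n(self, rng):
        a = rng.integers(0, 3, 150_000)
        b = rng.integers(0, 3, 150_000)
        assert channel_redundancy(binned(a, b), 0) == pytest.approx(0.0, abs=0.02)

    def test_matches_brute_force_all_subsets(self, tiny_binned):
        cols = [tiny_binned.bins[:, k].tolist() for k in range(3)]
        for size in (2, 3):
            for subset in itertools.combinations(range(3), size):
                sub = binned(*[cols[k] for k in subset])
                for pos in range(size):
                    assert channel_redundancy(sub, pos) == pytest.approx(
                        brute_channel_redundancy([cols[k] for k in subset], pos)
                    )

    def test_constant_channel_undefined(self):
        ch = binned([1] * 8, [0, 1] * 4)
        with pytest.raises(UndefinedValueError):
            channel_redundancy(ch, 0)

    def test_single_channel_rejected(self):
        with pytest.raises(ContractError, match="2 channels"):
            channel_redundancy(binned([0, 1, 0]), 0)

    def test_log_base_invariant(self, tiny_record):
        b2 = bin_record(tiny_record, BinningConfig(log_base=2.0))
        be = bin_record(tiny_record, BinningConfig(log_base=math.e))
        for i in range(3):
            assert channel_redundancy(b2, i) == pytest.approx(
                channel_redundancy(be, i), abs=1e-9
            )


class TestSetRedundancy:
    def test_single_channel_zero(self, rng):
        assert set_redundancy(binned(rng.integers(0, 5, 100))) == 0.0

    def test_exact_copy_pair_fully_redundant(self, rng):
        col = rng.integers(0, 4, 60)
        assert set_redundancy(binned(col, col)) == pytest.approx(1.0)

    def test_independent_channels_near_zero_large_n(self, rng):
        cols = [rng.integers(0, 3, 120_000) for _ in range(3)]
        assert set_redundancy(binned(*cols)) == pytest.approx(0.0, abs=0.02)

    def test_matches_brute_force_all_subsets(self, tiny_binned):
        cols = [tiny_binned.bins[:, k].tolist() for k in range(3)]
        for size in (2, 3):
            for subset in itertools.combinations(range(3), size):
                assert set_redundancy(tiny_binned, list(subset)) == pytest.approx(
                    brute_set_redundancy([cols[k] for k in subset])
                )

    def test_all_constant_undefined(self):
        with pytest.raises(UndefinedValueError):
            set_redundancy(binned([2] * 6, [5] * 6))

    def test_log_base_invariant(self, tiny_record):
        b2 = bin_record(tiny_record, BinningConfig(log_base=2.0))
        be = bin_record(tiny_record, BinningConfig(log_base=math.e))
        assert set_redundancy(b2) == pytest.approx(set_redundancy(be), abs=1e-9)

    def test_bias_shrinks_with_sample_count(self):
        # plug-in overestimation of shared information for independent
        # channels fades as the joint histogram fills in
        rng = np.random.default_rng(99)
        values = []
        for n in (10**3, 10**4, 10**5):
            cols = [rng.integers(0, 4, n) for _ in range(3)]
            values.append(set_redundancy(binned(*cols)))
        assert values[0] > values[1] > values[2]


class TestConditionalEntropy:
    def test_chain_rule_against_brute_force(self, tiny_binned):
        cols = [tiny_binned.bins[:, k].tolist() for k in range(3)]
        assert conditional_entropy(tiny_binned, [0], [1, 2]) == pytest.approx(
            brute_conditional_entropy([cols[0]], [cols[1], cols[2]])
        )

    def test_overlapping_subsets_rejected(self, tiny_binned):
        with pytest.raises(ContractError, match="overlap"):
            conditional_entropy(tiny_binned, [0], [0, 1])


class TestPcc:
    def test_self_correlation_one(self, tiny_record):
        assert pcc(tiny_record, 0, 0) == pytest.approx(1.0)

    def test_negation_minus_one(self, rng):
        x = rng.normal(size=100)
        rec = MultichannelRecord(("A", "B"), np.column_stack([x, -x]))
        assert pcc(rec, "A", "B") == pytest.approx(-1.0)

    def test_sine_cosine_orthogonal(self):
        t = np.linspace(0, 4 * np.pi, 4000, endpoint=False)
        rec = MultichannelRecord(("s", "c"), np.column_stack([np.sin(t), np.cos(t)]))
        assert abs(pcc(rec, 0, 1)) < 1e-6

    def test_zero_variance_undefined(self):
        rec = MultichannelRecord(("A", "B"), np.column_stack([np.ones(10), np.arange(10.0)]))
        with pytest.raises(UndefinedValueError, match="'A'"):
            pcc(rec, 0, 1)


class TestRedundancyReport:
    def test_report_values_consistent(self, tiny_record):
        rep = redundancy_report(tiny_record)
        ch = bin_record(tiny_record)
        assert rep.set_R == pytest.approx(set_redundancy(ch))
        for i, r in enumerate(rep.per_channel_R):
            assert r == pytest.approx(channel_redundancy(ch, i))
        assert rep.n_samples == tiny_record.n_samples

    def test_percent_scaling(self, tiny_record):
        rep = redundancy_report(tiny_record)
        d = rep.as_dict(percent=True)
        assert d["set_R"] == pytest.approx(rep.set_R * 100)
        assert d["scale"] == "percent"
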