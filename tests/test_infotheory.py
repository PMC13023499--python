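"""Equal-frequency binning, entropy/MI estimators and significance tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edafaa.infotheory import (DiscreteJointDistribution, bonferroni_threshold,
                               entropy, equal_frequency_bins,
                               joint_distribution, mi_equal_frequency,
                               mutual_information_mm,
                               mutual_information_plugin, pearson_screen,
                               permutation_test_mi)
from edafaa.infotheory import _mi_from_assignments, _mm_correction_bits

LOG2_12 = math.log2(12)


class TestEqualFrequencyBins:
    def test_127_samples_12_bins_counts_near_uniform(self, rng):
        b = equal_frequency_bins(rng.normal(size=127), 12)
        assert set(b.counts.tolist()) == {10, 11}
        assert np.isclose(10 / 127, b.probabilities.min())
        assert b.counts.sum() == 127

    def test_one_sample_per_bin_when_n_equals_bins(self, rng):
        b = equal_frequency_bins(rng.permutation(12).astype(float), 12)
        assert np.all(b.counts == 1)
        assert np.allclose(b.probabilities, 1 / 12)

    def test_monotone_transform_preserves_assignments(self, rng):
        x = rng.normal(size=200)
        a = equal_frequency_bins(x, 12).assignments
        b = equal_frequency_bins(x ** 3, 12).assignments  # strictly monotone
        assert np.array_equal(a, b)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            equal_frequency_bins(np.ones(50), 12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(n=st.integers(24, 400), n_bins=st.integers(2, 12))
    def test_counts_differ_by_at_most_one(self, n, n_bins):
        x = np.random.default_rng(n * 31 + n_bins).normal(size=n)
        b = equal_frequency_bins(x, n_bins)
        assert b.counts.sum() == n
        assert b.counts.max() - b.counts.min() <= 1
        assert b.assignments.min() >= 0 and b.assignments.max() < n_bins


class TestEntropy:
    @pytest.mark.parametrize("p, expected", [
        (np.full(12, 1 / 12), LOG2_12),
        ([1.0, 0.0, 0.0], 0.0),
        ([0.5, 0.5], 1.0),
    ])
    def test_analytic_values(self, p, expected):
        assert entropy(p) == pytest.approx(expected, abs=1e-12)

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            entropy([1.2, -0.2])

    def test_equal_frequency_binning_maximizes_marginal_entropy(self, rng):
        # uniform-count bins keep H within 0.02 bits of log2(B) even when
        # B does not divide N
        b = equal_frequency_bins(rng.normal(size=1187), 12)
        assert entropy(b.probabilities) > LOG2_12 - 0.02


class TestJointDistribution:
    def test_same_variable_gives_diagonal_joint(self, rng):
        x = rng.normal(size=120)
        bx = equal_frequency_bins(x, 6)
        j = joint_distribution(bx, bx)
        assert np.all(j.joint_counts == np.diag(np.diag(j.joint_counts)))

    def test_marginals_equal_binning_probabilities(self, rng):
        x, y = rng.normal(size=(2, 127))
        bx, by = equal_frequency_bins(x, 12), equal_frequency_bins(y, 12)
        j = joint_distribution(bx, by)
        assert np.allclose(j.marginal_px, bx.probabilities)
        assert np.allclose(j.marginal_py, by.probabilities)

    def test_matches_brute_force_double_loop(self, rng):
        x, y = rng.normal(size=(2, 20))
        bx, by = equal_frequency_bins(x, 4), equal_frequency_bins(y, 4)
        j = joint_distribution(bx, by)
        expected = np.zeros((4, 4), dtype=int)
        for k in range(20):
            expected[bx.assignments[k], by.assignments[k]] += 1
        assert np.array_equal(j.joint_counts, expected)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            joint_distribution(equal_frequency_bins(rng.normal(size=24), 4),
                               equal_frequency_bins(rng.normal(size=25), 4))


def _make_joint(joint_p):
    joint_p = np.asarray(joint_p, dtype=float)
    return DiscreteJointDistribution(
        joint_counts=(joint_p * 1000).astype(int), joint_p=joint_p,
        marginal_px=joint_p.sum(axis=1), marginal_py=joint_p.sum(axis=0))


class TestPluginMI:
    def test_independent_product_distribution_is_zero(self):
        px = np.array([0.2, 0.3, 0.5])
        py = np.array([0.6, 0.4])
        assert mutual_information_plugin(_make_joint(np.outer(px, py))) == \
            pytest.approx(0.0, abs=1e-12)

    def test_identity_joint_equals_marginal_entropy(self):
        j = _make_joint(np.eye(12) / 12)
        assert mutual_information_plugin(j) == pytest.approx(LOG2_12, abs=1e-12)

    def test_matches_brute_force_shannon_sum(self, rng):
        p = rng.random((5, 5))
        p /= p.sum()
        j = _make_joint(p)
        px, py = p.sum(axis=1), p.sum(axis=0)
        expected = sum(p[i, k] * math.log2(p[i, k] / (px[i] * py[k]))
                       for i in range(5) for k in range(5) if p[i, k] > 0)
        assert mutual_information_plugin(j) == pytest.approx(expected, rel=1e-12)


class TestMillerMadow:
    def test_full_table_correction_value_at_n127(self):
        # (144 - 12 - 12 + 1) / (2 * 127 * ln 2), evaluated directly
        assert _mm_correction_bits(144, 12, 12, 127) == \
            pytest.approx(0.687268, abs=1e-6)

    @pytest.mark.parametrize("n", [127, 1296])
    def test_copy_case_equals_entropy_minus_correction(self, rng, n):
        x = rng.normal(size=n)
        r = mi_equal_frequency(x, x, 12)
        h = entropy(equal_frequency_bins(x, 12).probabilities)
        assert r.plugin_bits == pytest.approx(h, abs=1e-9)
        assert r.corrected_bits == pytest.approx(h - r.correction_bits, abs=1e-9)
        assert h > LOG2_12 - 0.02

    def test_independent_data_corrected_mi_consistent_with_null(self):
        """At the sparse N=127, B=12 regime the corrected MI of independent
        draws stays within 3 permutation-null SDs of zero on average."""
        rng = np.random.default_rng(7)
        vals, null_sds = [], []
        for _ in range(20):
            x, y = rng.normal(size=(2, 127))
            r = mi_equal_frequency(x, y, 12)
            assert r.plugin_bits > 0
            ax = equal_frequency_bins(x, 12).assignments
            ay = equal_frequency_bins(y, 12).assignments
            null = [_mi_from_assignments(ax, ay[rng.permutation(127)],
                                         12, 12, 127)[1] for _ in range(200)]
            vals.append(r.corrected_bits)
            null_sds.append(np.std(null))
        assert abs(np.mean(vals)) <= 3 * np.mean(null_sds)

    def test_symmetry_and_floor(self, rng):
        x, y = rng.normal(size=(2, 300))
        assert mutual_information_mm(x, y) == pytest.approx(
            mutual_information_mm(y, x), abs=1e-12)
        assert mutual_information_mm(x, y) >= 0.0

    def test_mi_decreases_as_noise_grows(self):
        """Dependence dilution: adding noise to y lowers MI in expectation."""
        rng = np.random.default_rng(11)
        means = []
        for sd in (0.1, 1.0, 5.0):
            vals = [mutual_information_mm(x, x + sd * rng.normal(size=500))
                    for x in rng.normal(size=(20, 500))]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestPermutationTest:
    def test_perfect_dependence_attains_the_add_one_floor(self, rng):
        x = rng.normal(size=500)
        mi, p = permutation_test_mi(x, x, n_perm=10_000, seed=3)
        assert p == pytest.approx(1 / 10_001)
        assert p < 0.0002
        assert mi > 3.0

    def test_type_one_error_calibration(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            x, y = r.normal(size=(2, 120))
            _, p = permutation_test_mi(x, y, n_perm=99, seed=seed)
            hits += p <= 0.05
        assert 0.01 <= hits / 100 <= 0.12

    def test_p_value_invariant_to_monotone_transform(self, rng):
        x, y = rng.normal(size=(2, 200))
        _, p1 = permutation_test_mi(x, y, n_perm=200, seed=5)
        _, p2 = permutation_test_mi(x, np.exp(y), n_perm=200, seed=5)
        assert p1 == p2

    def test_block_permutation_runs(self, rng):
        x, y = rng.normal(size=(2, 200))
        _, p = permutation_test_mi(x, y, n_perm=99, seed=5, block_len=20)
        assert 0 < p <= 1


class TestPearsonScreen:
    def test_linear_relation_gives_unit_correlation(self, rng):
        x = rng.normal(size=100)
        r, p = pearson_screen(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_symmetric_quadratic_escapes_linear_screen_but_not_mi(self, rng):
        """The motivating contrast: r ~ 0 while binned MI stays large."""
        x = np.concatenate([rng.normal(size=500), -rng.normal(size=500)])
        y = x ** 2
        r, _ = pearson_screen(x, y)
        assert abs(r) < 0.1
        assert mutual_information_mm(x, y, 12) > 0.5

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_screen(np.ones(10), np.arange(10.0))


class TestBonferroni:
    def test_six_comparisons_printed_value(self):
        assert round(bonferroni_threshold(0.05, 6), 4) == 0.0083

    def test_single_comparison_identity_and_exact_product(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 6) * 6 == 0.05
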