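import itertools
import math

import numpy as np
import pandas as pd
import pytest

from candex.essentiality import (
    MIFilterParams,
    cohens_d,
    differential_essentiality,
    mann_whitney,
    mean_essentiality_by_group,
    mi_filter,
    mutual_information,
)


def exact_mw_oracle(x, y):
    """Brute-force two-sided Mann-Whitney: enumerate all rank assignments.

    U for group x counts pairs (xi, yj) with xi > yj; the p-value is the
    probability, over all C(n1+n2, n1) equally likely group labelings of the
    observed pooled values, of a U at least as extreme (two-sided, by
    min(P[U <= u], P[U >= u]) doubled and capped at 1).
    """
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        gx = [pooled[i] for i in combo]
        gy = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(sum(1 for xi in gx for yj in gy if xi > yj))
    us = np.array(us)
    p_low = (us <= u_obs).mean()
    p_high = (us >= u_obs).mean()
    return u_obs, min(1.0, 2 * min(p_low, p_high))


class TestMannWhitney:
    def test_separated_triplets(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 * 1/20 over C(6,3) labelings

    def test_identical_groups_no_evidence(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p >= 0.99

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 7), rng.normal(1, 1, 5)
        u_xy, p_xy = mann_whitney(x, y)
        u_yx, p_yx = mann_whitney(y, x)
        assert p_xy == pytest.approx(p_yx)
        assert u_yx == pytest.approx(len(x) * len(y) - u_xy)

    def test_empty_group_untestable_not_exception(self):
        u, p = mann_whitney([], [1.0, 2.0])
        assert math.isnan(u) and math.isnan(p)

    def test_nans_dropped_pairwise(self):
        u1, p1 = mann_whitney([1, 2, np.nan, 3], [4, np.nan, 5, 6])
        u2, p2 = mann_whitney([1, 2, 3], [4, 5, 6])
        assert (u1, p1) == (u2, p2)

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 3), (3, 5), (4, 4),
                                       (5, 6), (6, 6), (1, 6), (6, 1)])
    def test_exact_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(20):
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 1, n2)
            u, p = mann_whitney(x, y, mode="exact")
            u_ref, p_ref = exact_mw_oracle(x, y)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)


class TestMutualInformation:
    def test_constant_vector_is_degenerate_zero(self):
        result = mutual_information([1.0] * 10, ["a"] * 5 + ["b"] * 5)
        assert result.score == 0.0 and result.degenerate

    def test_perfect_binary_separation_is_ln2(self):
        values = [1, 2, 3, 4, 10, 11, 12, 13]
        labels = ["a"] * 4 + ["b"] * 4
        result = mutual_information(values, labels, bins=2)
        assert result.score == pytest.approx(math.log(2), rel=1e-9)
        assert not result.degenerate

    def test_permuted_values_fall_in_null_band(self):
        """MI of randomly relabeled values stays near the permutation null."""
        rng = np.random.default_rng(9)
        values = rng.normal(0, 1, 40)
        labels = np.array(["a"] * 20 + ["b"] * 20)
        null = []
        for _ in range(1000):
            null.append(mutual_information(values, rng.permutation(labels),
                                           bins=4).score)
        null = np.array(null)
        observed = mutual_information(values, rng.permutation(labels), bins=4).score
        assert observed <= np.quantile(null, 0.999)
        # plug-in MI is biased up but small: the null band sits near zero
        assert np.median(null) < 0.2

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        values = rng.normal(0, 1, 30)
        labels = list(rng.choice(["a", "b", "c"], 30))
        base = mutual_information(values, labels, bins=5).score
        for transform in (np.exp, lambda v: v ** 3, lambda v: 2 * v + 7):
            assert mutual_information(transform(values), labels, bins=5
                                      ).score == pytest.approx(base, rel=1e-9)

    def test_mi_nonnegative(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            values = rng.normal(0, 1, 20)
            labels = list(rng.choice(["a", "b"], 20))
            assert mutual_information(values, labels).score >= 0


class TestMIFilter:
    def test_identical_scores_remove_nothing(self):
        # constant-MI field: sd = 0 and strict inequality keeps everything
        matrix = pd.DataFrame(np.tile([1.0, 2.0, 3.0, 4.0], (10, 1)),
                              index=[f"g{i}" for i in range(10)])
        kept, removed, _ = mi_filter(matrix, ["a", "a", "b", "b"], bins=2)
        assert removed == [] and len(kept) == 10

    def test_planted_extreme_mi_genes_removed(self):
        rng = np.random.default_rng(12)
        n_lines = 40
        labels = ["a"] * 20 + ["b"] * 20
        rows = {f"null{i:03d}": rng.normal(0, 1, n_lines) for i in range(95)}
        for i in range(5):
            # perfectly separated by the covariate: MI far above the field
            rows[f"hot{i}"] = np.array([0.0] * 20 + [10.0] * 20) + rng.normal(0, 0.01, n_lines)
        matrix = pd.DataFrame(rows).T
        kept, removed, scores = mi_filter(matrix, labels, bins=2)
        assert set(removed) == {f"hot{i}" for i in range(5)}
        assert set(kept) | set(removed) == set(matrix.index)


class TestCohensD:
    def test_shifted_triplets(self):
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_equal_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_constant_equal_groups_undefined(self):
        assert math.isnan(cohens_d([2, 2, 2], [2, 2, 2]))

    def test_single_observation_undefined(self):
        assert math.isnan(cohens_d([1], [2, 3]))


class TestDifferentialEssentiality:
    def make_matrix(self, seed=0, n_genes=60, shift_genes=5, delta=-1.0,
                    n_per_group=8, sigma=0.15):
        rng = np.random.default_rng(seed)
        lines = [f"L{i:02d}" for i in range(2 * n_per_group)]
        values = rng.normal(0, sigma, (n_genes, len(lines)))
        values[:shift_genes, :n_per_group] += delta
        matrix = pd.DataFrame(values, index=[f"g{i:03d}" for i in range(n_genes)],
                              columns=lines)
        return matrix, lines[:n_per_group], lines[n_per_group:]

    def test_overlapping_groups_rejected(self):
        matrix, a, b = self.make_matrix()
        with pytest.raises(ValueError, match="disjoint"):
            differential_essentiality(matrix, a, a)

    def test_planted_shift_recovered(self):
        matrix, a, b = self.make_matrix()
        result = differential_essentiality(
            matrix, a, b, alpha=0.01, mi_params=MIFilterParams(enabled=False))
        significant = set(result.loc[result["significant"], "gene"])
        assert {f"g{i:03d}" for i in range(5)} <= significant
        top = result.head(5)
        assert top["mean_diff"].lt(-0.5).all()

    def test_result_invariant_to_input_ordering(self):
        matrix, a, b = self.make_matrix(seed=3)
        rng = np.random.default_rng(8)
        shuffled = matrix.iloc[rng.permutation(len(matrix)),
                               rng.permutation(matrix.shape[1])]
        r1 = differential_essentiality(matrix, a, b,
                                       mi_params=MIFilterParams(enabled=False))
        r2 = differential_essentiality(shuffled, list(reversed(a)), b,
                                       mi_params=MIFilterParams(enabled=False))
        pd.testing.assert_frame_equal(r1, r2)

    def test_group_swap_negates_mean_diff(self):
        matrix, a, b = self.make_matrix(seed=6)
        r_ab = differential_essentiality(matrix, a, b,
                                         mi_params=MIFilterParams(enabled=False))
        r_ba = differential_essentiality(matrix, b, a,
                                         mi_params=MIFilterParams(enabled=False))
        merged = r_ab.set_index("gene").join(r_ba.set_index("gene"),
                                             rsuffix="_swapped")
        assert np.allclose(merged["mean_diff"], -merged["mean_diff_swapped"])
        assert np.allclose(merged["p"], merged["p_swapped"])

    def test_mi_filter_column_reported(self):
        matrix, a, b = self.make_matrix(seed=2, n_genes=30)
        result = differential_essentiality(matrix, a, b,
                                           mi_params=MIFilterParams(bins=4))
        assert result["mi"].notna().all()
        removed = result[~result["mi_pass"]]
        assert removed["p"].isna().all()  # no test for filtered genes


class TestMeanEssentialityByGroup:
    def test_single_line_groups_equal_raw_values(self):
        matrix = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]],
                              index=["g1", "g2"], columns=["L1", "L2"])
        means = mean_essentiality_by_group(matrix, {"a": ["L1"], "b": ["L2"]})
        assert means.loc["g1", "a"] == 1.0 and means.loc["g2", "b"] == 4.0
        assert means.loc["g1", "deviation"] == -1.0

    def test_shifted_gene_has_largest_deviation(self):
        rng = np.random.default_rng(7)
        values = rng.normal(0, 0.05, (20, 10))
        values[4, :5] -= 2.0  # shifted only in the first group
        matrix = pd.DataFrame(values, index=[f"g{i}" for i in range(20)],
                              columns=[f"L{i}" for i in range(10)])
        means = mean_essentiality_by_group(
            matrix, {"mut": [f"L{i}" for i in range(5)],
                     "wt": [f"L{i}" for i in range(5, 10)]})
        assert means["deviation"].abs().idxmax() == "g4"

    def test_group_swap_negates_deviation(self):
        matrix = pd.DataFrame(np.arange(8.0).reshape(2, 4),
                              index=["g1", "g2"],
                              columns=["L1", "L2", "L3", "L4"])
        fwd = mean_essentiality_by_group(matrix, {"a": ["L1", "L2"], "b": ["L3", "L4"]})
        rev = mean_essentiality_by_group(matrix, {"b": ["L3", "L4"], "a": ["L1", "L2"]})
        assert np.allclose(fwd["deviation"], -rev["deviation"])

    def test_missing_gene_in_group_yields_missing_cell(self):
        matrix = pd.DataFrame([[np.nan, 2.0]], index=["g1"], columns=["L1", "L2"])
        means = mean_essentiality_by_group(matrix, {"a": ["L1"], "b": ["L2"]})
        assert math.isnan(means.loc["g1", "a"]) and means.loc["g1", "b"] == 2.0
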