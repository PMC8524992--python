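import math

import numpy as np
import pandas as pd
import pytest

from candex.mutscreen import (
    DriverSpec,
    binarize_bayes_factors,
    chi_square_2x2,
    followup_effect_sizes,
    mutation_indicator,
    run_pair_screen,
    select_variable_genes,
)


def closed_form_chi2(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestBinarize:
    @pytest.mark.parametrize("bf,expected", [(5.1, 1.0), (5.0, 0.0), (4.9, 0.0)])
    def test_cutoff_boundary(self, bf, expected):
        matrix = pd.DataFrame([[bf]], index=["g"], columns=["L"])
        assert binarize_bayes_factors(matrix).iloc[0, 0] == expected

    def test_missing_stays_missing(self):
        matrix = pd.DataFrame([[np.nan, 7.0]], index=["g"], columns=["L1", "L2"])
        out = binarize_bayes_factors(matrix)
        assert math.isnan(out.iloc[0, 0]) and out.iloc[0, 1] == 1.0


class TestVariableGeneSelection:
    def make_binary(self, n_genes=1000, n_lines=30, seed=0):
        rng = np.random.default_rng(seed)
        probs = rng.uniform(0, 1, n_genes)
        values = (rng.uniform(size=(n_genes, n_lines)) < probs[:, None]).astype(float)
        return pd.DataFrame(values, index=[f"g{i:04d}" for i in range(n_genes)],
                            columns=[f"L{j}" for j in range(n_lines)])

    def test_band_arithmetic_exact_count(self):
        matrix = self.make_binary()
        assert len(select_variable_genes(matrix, (0.85, 0.95))) == 100

    def test_monotone_nesting_of_upper_bands(self):
        matrix = self.make_binary(seed=3)
        inner = set(select_variable_genes(matrix, (0.90, 0.95)))
        outer = set(select_variable_genes(matrix, (0.85, 0.95)))
        widest = set(select_variable_genes(matrix, (0.80, 1.00)))
        assert inner <= outer <= widest

    def test_all_constant_genes_still_return_band_by_rank(self):
        matrix = pd.DataFrame(np.zeros((100, 10)),
                              index=[f"g{i:03d}" for i in range(100)],
                              columns=[f"L{j}" for j in range(10)])
        selected = select_variable_genes(matrix, (0.90, 1.00))
        assert len(selected) == 10
        # tie-break by gene id: the last 10 ids in sorted order
        assert selected == [f"g{i:03d}" for i in range(90, 100)]

    def test_planted_maximal_variance_genes_selected(self):
        rng = np.random.default_rng(5)
        low = (rng.uniform(size=(90, 20)) < 0.05).astype(float)
        high = np.tile([0.0, 1.0], (10, 10))  # variance is maximal at p=0.5
        matrix = pd.DataFrame(np.vstack([low, high]),
                              index=[f"g{i:03d}" for i in range(100)],
                              columns=[f"L{j}" for j in range(20)])
        selected = select_variable_genes(matrix, (0.90, 1.00))
        assert set(selected) == {f"g{i:03d}" for i in range(90, 100)}

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            select_variable_genes(self.make_binary(n_genes=10), (0.9, 1.5))


class TestMutationIndicator:
    @pytest.fixture
    def mutations(self):
        return pd.DataFrame({
            "gene": ["KRAS", "KRAS", "TP53"],
            "line_id": ["L1", "L2", "L3"],
            "variant_class": ["Missense_Mutation", "Missense_Mutation",
                              "Nonsense_Mutation"],
            "protein_change": ["G12D", "G13D", "R196*"],
        })

    def test_onco_missense_matches_specific_change(self, mutations):
        driver = DriverSpec("KRAS", "onco_missense", ("G12D",))
        ind = mutation_indicator(driver, ["L1", "L2", "L3"], mutations)
        assert list(ind) == [1, 0, 0]

    def test_tsg_nonsense_matches_any_nonsense(self, mutations):
        driver = DriverSpec("TP53", "tsg_nonsense")
        ind = mutation_indicator(driver, ["L1", "L2", "L3"], mutations)
        assert list(ind) == [0, 0, 1]

    def test_driver_spec_validation(self):
        with pytest.raises(ValueError):
            DriverSpec("KRAS", "onco_missense", ())
        with pytest.raises(ValueError):
            DriverSpec("TP53", "tsg_nonsense", ("R196*",))


class TestChiSquare:
    def test_known_table(self):
        chi2, p, expected_min = chi_square_2x2([[20, 5], [5, 20]])
        assert chi2 == pytest.approx(18.0)
        assert expected_min == pytest.approx(12.5)
        assert 0 < p < 1e-4

    def test_independence_table(self):
        chi2, p, _ = chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == 1.0

    def test_zero_margin_untestable(self):
        chi2, p, _ = chi_square_2x2([[5, 0], [0, 0]])
        assert math.isnan(chi2) and math.isnan(p)

    def test_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 1000:
            a, b, c, d = rng.integers(0, 50, 4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            chi2, _, _ = chi_square_2x2([[a, b], [c, d]])
            ref = closed_form_chi2(a, b, c, d)
            assert chi2 == pytest.approx(ref, rel=1e-9, abs=1e-12)
            checked += 1

    def test_perfect_association_reaches_n_by_enumeration(self):
        """Among same-margin tables, the perfect diagonal attains chi2 = N."""
        for half in range(1, 11):  # N = 2*half <= 20
            best = 0.0
            for a in range(half + 1):
                table = [[a, half - a], [half - a, a]]
                chi2, _, _ = chi_square_2x2(table)
                if not math.isnan(chi2):
                    best = max(best, chi2)
            assert best == pytest.approx(2 * half)
            perfect, _, _ = chi_square_2x2([[half, 0], [0, half]])
            assert perfect == pytest.approx(2 * half)


class TestPairScreen:
    def make_screen_inputs(self, seed=0, n_genes=10, n_lines=40):
        rng = np.random.default_rng(seed)
        lines = [f"L{i:02d}" for i in range(n_lines)]
        matrix = pd.DataFrame(
            rng.integers(0, 2, (n_genes, n_lines)).astype(float),
            index=[f"g{i:02d}" for i in range(n_genes)], columns=lines)
        mut_lines = lines[: n_lines // 2]
        mutations = pd.DataFrame({
            "gene": ["D1"] * len(mut_lines),
            "line_id": mut_lines,
            "variant_class": ["Nonsense_Mutation"] * len(mut_lines),
            "protein_change": [""] * len(mut_lines),
        })
        return matrix, mutations, lines

    def test_pair_cardinality(self):
        matrix, mutations, _ = self.make_screen_inputs()
        drivers = [DriverSpec("D1", "tsg_nonsense"),
                   DriverSpec("D2", "tsg_nonsense"),
                   DriverSpec("D3", "tsg_nonsense")]
        screen = run_pair_screen(matrix, drivers, list(matrix.index), mutations)
        assert len(screen) == 30

    def test_planted_perfect_association_has_minimal_p(self):
        matrix, mutations, lines = self.make_screen_inputs(seed=1)
        # essentiality of gE equals mutation status of D1 exactly (20/20)
        matrix.loc["g00"] = [1.0] * 20 + [0.0] * 20
        drivers = [DriverSpec("D1", "tsg_nonsense")]
        screen = run_pair_screen(matrix, drivers, list(matrix.index), mutations)
        best = screen.loc[screen["p"].idxmin()]
        assert best["ess_gene"] == "g00"
        assert best["chi2"] == pytest.approx(40.0)  # chi2 = N for perfect 2x2

    def test_alpha_zero_flags_nothing(self):
        matrix, mutations, _ = self.make_screen_inputs(seed=2)
        drivers = [DriverSpec("D1", "tsg_nonsense")]
        screen = run_pair_screen(matrix, drivers, list(matrix.index), mutations,
                                 alpha=0.0)
        assert not screen["significant"].any()

    def test_screen_invariant_to_orderings(self):
        matrix, mutations, _ = self.make_screen_inputs(seed=3)
        drivers = [DriverSpec("D1", "tsg_nonsense")]
        rng = np.random.default_rng(0)
        shuffled = matrix.iloc[rng.permutation(len(matrix)),
                               rng.permutation(matrix.shape[1])]
        s1 = run_pair_screen(matrix, drivers, sorted(matrix.index), mutations)
        s2 = run_pair_screen(shuffled, drivers, sorted(matrix.index), mutations)
        pd.testing.assert_frame_equal(s1, s2)

    def test_null_screen_rejection_rate_in_binomial_band(self):
        rng = np.random.default_rng(11)
        n_genes, n_lines = 400, 60
        matrix = pd.DataFrame(
            rng.integers(0, 2, (n_genes, n_lines)).astype(float),
            index=[f"g{i:03d}" for i in range(n_genes)],
            columns=[f"L{i:02d}" for i in range(n_lines)])
        mut_lines = [f"L{i:02d}" for i in rng.choice(n_lines, 25, replace=False)]
        mutations = pd.DataFrame({
            "gene": ["D1"] * 25, "line_id": mut_lines,
            "variant_class": ["Nonsense_Mutation"] * 25,
            "protein_change": [""] * 25})
        screen = run_pair_screen(matrix, [DriverSpec("D1", "tsg_nonsense")],
                                 list(matrix.index), mutations, alpha=0.01)
        testable = screen[screen["testable"]]
        rate = testable["significant"].mean()
        # binomial 99% band around 0.01 with 400 pairs: [0, ~0.025]
        assert rate <= 0.025


class TestFollowup:
    def test_planted_ceres_shift_gives_large_cohens_d(self):
        rng = np.random.default_rng(21)
        lines = [f"L{i:02d}" for i in range(40)]
        mut_lines = lines[:20]
        mutations = pd.DataFrame({
            "gene": ["D1"] * 20, "line_id": mut_lines,
            "variant_class": ["Nonsense_Mutation"] * 20,
            "protein_change": [""] * 20})
        bin_matrix = pd.DataFrame(
            [[1.0] * 20 + [0.0] * 20], index=["gE"], columns=lines)
        ceres = pd.DataFrame(
            [np.concatenate([rng.normal(-0.8, 0.3, 20), rng.normal(0, 0.3, 20)])],
            index=["gE"], columns=lines)
        drivers = [DriverSpec("D1", "tsg_nonsense")]
        screen = run_pair_screen(bin_matrix, drivers, ["gE"], mutations)
        groups = followup_effect_sizes(screen, ceres, drivers, mutations)
        row = groups["tsg"].iloc[0]
        assert abs(row["cohens_d"]) >= 2.0
        assert row["mean_diff"] < -0.5
        assert row["mw_p"] < 1e-4
        assert groups["onco"].empty
        assert len(groups["combined"]) == 1

    def test_identical_distributions_give_zero_effect(self):
        lines = [f"L{i}" for i in range(8)]
        mutations = pd.DataFrame({
            "gene": ["D1"] * 4, "line_id": lines[:4],
            "variant_class": ["Nonsense_Mutation"] * 4,
            "protein_change": [""] * 4})
        bin_matrix = pd.DataFrame([[1, 1, 0, 0, 1, 1, 0, 0]], index=["gE"],
                                  columns=lines, dtype=float)
        screen = run_pair_screen(bin_matrix, [DriverSpec("D1", "tsg_nonsense")],
                                 ["gE"], mutations, alpha=1.1)
        ceres = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0]],
                             index=["gE"], columns=lines)
        groups = followup_effect_sizes(screen, ceres,
                                       [DriverSpec("D1", "tsg_nonsense")], mutations)
        row = groups["combined"].iloc[0]
        assert row["cohens_d"] == pytest.approx(0.0)
        assert row["mw_p"] >= 0.99

    def test_self_pair_labeled_in_onco_group(self):
        lines = [f"L{i}" for i in range(20)]
        mutations = pd.DataFrame({
            "gene": ["KRAS"] * 10, "line_id": lines[:10],
            "variant_class": ["Missense_Mutation"] * 10,
            "protein_change": ["G12D"] * 10})
        bin_matrix = pd.DataFrame([[1.0] * 10 + [0.0] * 10], index=["KRAS"],
                                  columns=lines)
        rng = np.random.default_rng(2)
        ceres = pd.DataFrame(
            [np.concatenate([rng.normal(-1.5, 0.1, 10), rng.normal(0, 0.1, 10)])],
            index=["KRAS"], columns=lines)
        drivers = [DriverSpec("KRAS", "onco_missense", ("G12D",))]
        screen = run_pair_screen(bin_matrix, drivers, ["KRAS"], mutations)
        assert screen["self_pair"].all()
        groups = followup_effect_sizes(screen, ceres, drivers, mutations)
        row = groups["onco"].iloc[0]
        assert row["self_pair"] and row["mean_diff"] < 0
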