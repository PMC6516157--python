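import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from agecap import de_core
from agecap.de_core import (
    ContrastSpec,
    adjust_bh,
    call_degs,
    estimate_dispersions,
    estimate_size_factors,
    wald_contrast,
)
from agecap.errors import ContractViolation, NormalizationError


def two_group_sheet(columns, n_a=3):
    return pd.DataFrame(
        {
            "sample_id": list(columns),
            "genotype": ["A"] * n_a + ["B"] * (len(columns) - n_a),
            "day": 1,
            "replicate": list(range(1, n_a + 1)) + list(range(1, len(columns) - n_a + 1)),
        }
    )


SPEC_AB = ContrastSpec("A_vs_B", {"genotype": "A"}, {"genotype": "B"})


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 9, 20], "b": [5, 9, 20], "c": [5, 9, 20]})
        np.testing.assert_allclose(estimate_size_factors(counts), 1.0)

    def test_hand_computed_median_of_ratios(self):
        counts = pd.DataFrame([[10, 20], [100, 200], [4, 8]], columns=["a", "b"])
        factors = estimate_size_factors(counts)
        np.testing.assert_allclose(factors, [0.7071, 1.4142], atol=5e-5)

    def test_scaling_one_sample_is_equivariant_up_to_the_reference(self, rng):
        # the geometric-mean reference itself absorbs a 5**(1/n) shift, so the
        # exact equivariance is on factor ratios: sample c gains a factor 5
        counts = pd.DataFrame(
            rng.poisson(50, size=(200, 4)), columns=list("abcd")
        ) + 1
        base = estimate_size_factors(counts)
        scaled = counts.copy()
        scaled["c"] *= 5
        factors = estimate_size_factors(scaled)
        np.testing.assert_allclose(
            factors["c"] / factors["a"], 5 * base["c"] / base["a"], rtol=1e-12
        )
        np.testing.assert_allclose(
            factors["b"] / factors["d"], base["b"] / base["d"], rtol=1e-12
        )
        np.testing.assert_allclose(factors["c"], 5 ** (3 / 4) * base["c"], rtol=1e-12)

    def test_invariant_to_gene_and_sample_order(self, rng):
        counts = pd.DataFrame(rng.poisson(30, size=(100, 5)), columns=list("abcde")) + 1
        base = estimate_size_factors(counts)
        shuffled = counts.sample(frac=1, random_state=0)[list("ecadb")]
        factors = estimate_size_factors(shuffled)
        np.testing.assert_allclose(factors[base.index], base, rtol=1e-12)

    def test_no_reference_genes_raises(self):
        counts = pd.DataFrame({"a": [0, 3], "b": [5, 0]})
        with pytest.raises(NormalizationError):
            estimate_size_factors(counts)


class TestDispersions:
    def test_known_truth_is_recovered_within_factor_two(self, rng):
        mu, alpha_true = 100.0, 0.1
        lam = rng.gamma(1 / alpha_true, alpha_true * mu, size=(2000, 6))
        counts = pd.DataFrame(rng.poisson(lam), columns=list("abcdef"))
        sf = pd.Series(1.0, index=counts.columns)
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=counts.columns)
        alphas = estimate_dispersions(counts, sf, groups)
        assert 0.05 <= alphas.median() <= 0.2

    def test_underdispersed_counts_hit_the_floor(self):
        # constant within groups: within-group variance 0 -> clamps at the floor
        counts = pd.DataFrame(
            {"a": [500, 80], "b": [500, 80], "c": [520, 90], "d": [520, 90]}
        )
        sf = pd.Series(1.0, index=counts.columns)
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=counts.columns)
        alphas = estimate_dispersions(counts, sf, groups)
        assert (alphas < 1e-6).all()

    def test_identical_gene_rows_get_identical_alpha(self, rng):
        row = rng.poisson(60, size=6)
        counts = pd.DataFrame([row, row, rng.poisson(60, size=6)], columns=list("abcdef"))
        sf = pd.Series(1.0, index=counts.columns)
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=counts.columns)
        alphas = estimate_dispersions(counts, sf, groups)
        assert alphas.iloc[0] == alphas.iloc[1]

    def test_all_zero_gene_gets_positive_trend_alpha(self, rng):
        counts = pd.DataFrame(rng.poisson(40, size=(50, 4)), columns=list("abcd"))
        counts.iloc[0] = 0
        sf = pd.Series(1.0, index=counts.columns)
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=counts.columns)
        alphas = estimate_dispersions(counts, sf, groups)
        assert alphas.iloc[0] > 0


class TestWaldContrast:
    def test_identical_groups_give_null_result(self):
        counts = pd.DataFrame(
            [[10, 10, 10, 10, 10, 10], [3, 7, 5, 3, 7, 5]], columns=list("abcdef")
        )
        sheet = two_group_sheet(counts.columns)
        sf = pd.Series(1.0, index=counts.columns)
        alphas = pd.Series(0.05, index=counts.index)
        result = wald_contrast(counts, sheet, SPEC_AB, sf, alphas)
        np.testing.assert_allclose(result["log2_fc"], 0.0)
        np.testing.assert_allclose(result["p_raw"], 1.0)

    def test_all_zero_gene_is_reported_null(self):
        counts = pd.DataFrame(
            [[0, 0, 0, 0, 0, 0], [9, 11, 10, 30, 28, 33]], columns=list("abcdef")
        )
        sheet = two_group_sheet(counts.columns)
        sf = pd.Series(1.0, index=counts.columns)
        alphas = pd.Series(0.05, index=counts.index)
        result = wald_contrast(counts, sheet, SPEC_AB, sf, alphas)
        assert result.iloc[0]["log2_fc"] == 0.0 and result.iloc[0]["p_raw"] == 1.0
        assert result.iloc[1]["p_raw"] < 0.05

    def test_swapping_groups_negates_lfc_and_keeps_p(self, rng):
        counts = pd.DataFrame(rng.poisson(80, size=(100, 6)), columns=list("abcdef"))
        sheet = two_group_sheet(counts.columns)
        sf = estimate_size_factors(counts + 1)
        alphas = pd.Series(0.03, index=counts.index)
        forward = wald_contrast(counts, sheet, SPEC_AB, sf, alphas)
        backward = wald_contrast(
            counts, sheet, ContrastSpec("B_vs_A", {"genotype": "B"}, {"genotype": "A"}),
            sf, alphas,
        )
        np.testing.assert_allclose(backward["log2_fc"], -forward["log2_fc"], rtol=1e-12)
        np.testing.assert_allclose(backward["p_raw"], forward["p_raw"], rtol=1e-12)

    def test_planted_fourfold_change_is_recovered(self, rng):
        lam_a = rng.gamma(1 / 0.05, 0.05 * 400, size=(200, 3))
        lam_b = rng.gamma(1 / 0.05, 0.05 * 100, size=(200, 3))
        counts = pd.DataFrame(
            np.hstack([rng.poisson(lam_a), rng.poisson(lam_b)]), columns=list("abcdef")
        )
        sheet = two_group_sheet(counts.columns)
        sf = pd.Series(1.0, index=counts.columns)
        alphas = pd.Series(0.05, index=counts.index)
        result = wald_contrast(counts, sheet, SPEC_AB, sf, alphas)
        assert ((result["log2_fc"] > 1.5) & (result["log2_fc"] < 2.5)).mean() >= 0.9

    def test_small_group_violates_contract(self):
        counts = pd.DataFrame([[1, 2, 3]], columns=list("abc"))
        sheet = two_group_sheet(counts.columns, n_a=1)
        with pytest.raises(ContractViolation):
            wald_contrast(
                counts, sheet, SPEC_AB,
                pd.Series(1.0, index=counts.columns), pd.Series(0.1, index=counts.index),
            )


def bh_bruteforce(p):
    """Independent O(m^2) restatement of the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos - 1, m)
        ]
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted


class TestBH:
    def test_textbook_vector(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-15
        )

    def test_all_ones_and_singleton_are_fixed_points(self):
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)
        np.testing.assert_allclose(adjust_bh([0.37]), [0.37])

    def test_out_of_range_p_is_rejected(self):
        with pytest.raises(ContractViolation):
            adjust_bh([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_matches_bruteforce_definition(self, p_values):
        np.testing.assert_allclose(adjust_bh(p_values), bh_bruteforce(p_values), atol=1e-12)

    def test_matches_statsmodels_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(rng.integers(1, 200))
            _, expected, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(adjust_bh(p), expected, atol=1e-12)


class TestCallDegs:
    def make_result(self, rows):
        return pd.DataFrame(
            rows, columns=["log2_fc", "p_adj"],
            index=[f"g{i}" for i in range(len(rows))],
        ).assign(p_raw=lambda d: d.p_adj)

    def test_empty_result_gives_empty_sets(self):
        degs = call_degs(self.make_result([]), 0.05)
        assert degs.up == frozenset() and degs.down == frozenset()

    def test_boundary_is_strict(self):
        degs = call_degs(self.make_result([[1.2, 0.049], [0.8, 0.05]]), 0.05)
        assert degs.up == {"g0"} and degs.down == frozenset()

    def test_invalid_alpha_is_rejected(self):
        with pytest.raises(ContractViolation):
            call_degs(self.make_result([[1.0, 0.01]]), 1.5)

    def test_up_and_down_are_disjoint_by_sign(self):
        degs = call_degs(self.make_result([[1.0, 0.01], [-2.0, 0.001], [0.5, 0.9]]), 0.05)
        assert degs.up == {"g0"} and degs.down == {"g1"}
        assert not degs.up & degs.down


class TestAgainstDeseq2:
    """Cross-check against the established NB framework on a small fixture."""

    @pytest.fixture(scope="class")
    def fixture_counts(self):
        rng = np.random.default_rng(99)
        mu = np.r_[rng.lognormal(4, 1, 60)]
        lfc = np.zeros(60)
        lfc[:10] = rng.choice([-1.5, 1.5], 10)
        lam_a = rng.gamma(1 / 0.05, 0.05 * mu[:, None] * 2.0 ** lfc[:, None], size=(60, 3))
        lam_b = rng.gamma(1 / 0.05, 0.05 * mu[:, None], size=(60, 3))
        counts = pd.DataFrame(
            np.hstack([rng.poisson(lam_a), rng.poisson(lam_b)]) + 1,
            index=[f"g{i}" for i in range(60)],
            columns=list("abcdef"),
        )
        return counts

    def test_size_factors_match_pydeseq2(self, fixture_counts):
        from pydeseq2.preprocessing import deseq2_norm

        _, expected = deseq2_norm(fixture_counts.T)
        ours = estimate_size_factors(fixture_counts)
        np.testing.assert_allclose(ours.to_numpy(), np.asarray(expected).ravel(), rtol=1e-10)

    def test_fold_changes_agree_with_pydeseq2(self, fixture_counts):
        from pydeseq2.dds import DeseqDataSet

        metadata = pd.DataFrame({"condition": ["A"] * 3 + ["B"] * 3}, index=list("abcdef"))
        dds = DeseqDataSet(
            counts=fixture_counts.T, metadata=metadata,
            design="~condition", quiet=True,
        )
        dds.deseq2()
        reference = pd.Series(
            dds.varm["LFC"].iloc[:, -1] / np.log(2), index=fixture_counts.index
        )
        sheet = two_group_sheet(fixture_counts.columns)
        sf = estimate_size_factors(fixture_counts)
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=fixture_counts.columns)
        alphas = estimate_dispersions(fixture_counts, sf, groups)
        ours = wald_contrast(fixture_counts, sheet, SPEC_AB, sf, alphas)["log2_fc"]
        # sign conventions: pydeseq2 reports B-vs-A for alphabetical factors
        corr = np.corrcoef(ours, -reference)[0, 1]
        assert abs(corr) > 0.95
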