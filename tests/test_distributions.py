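"""Answer-category PMFs, exposure risk, and divergence measures.

The independent oracle for every PMF is exhaustive enumeration of all
2^(m+1) joint answer patterns weighted by their Bernoulli probabilities,
with the scenario transform applied pattern-by-pattern.
"""

import itertools

import numpy as np
import pytest

from sscount import (
    DesignError,
    answer_pmf,
    compare_distributions,
    exposure_probabilities,
    exposure_table,
)


def enumerated_pmf(m, d, scenario, probs=None):
    """Brute-force PMF over all 2^(m+1) answer patterns."""
    if probs is None:
        probs = [0.5] * m
    pmf = np.zeros(m + 2)
    for pattern in itertools.product([0, 1], repeat=m + 1):
        weight = 1.0
        for bit, p in zip(pattern, list(probs) + [d]):
            weight *= p if bit else (1.0 - p)
        total = sum(pattern)
        if scenario == "merge_top_bottom" and total == m + 1:
            pmf[0] += weight
        elif scenario == "any_other" and total == m + 1:
            pmf[: m + 1] += weight / (m + 1)
        else:
            pmf[total] += weight
    return pmf


class TestClosedForms:
    """The printed closed forms for the equal 4+1 design."""

    def test_no_sensitive_mass_is_plain_binomial(self):
        dist = answer_pmf(4, 0.0, "honest")
        assert dist.pmf[2] == pytest.approx(0.375, abs=1e-15)
        assert dist.pmf[5] == 0.0

    @pytest.mark.parametrize("d", [0.0, 0.2, 0.5, 1.0])
    def test_honest_category_forms(self, d):
        dist = answer_pmf(4, d, "honest")
        expected = [
            1 / 16 - d / 16,
            1 / 4 - 3 * d / 16,
            3 / 8 - d / 8,
            1 / 4 + d / 8,
            1 / 16 + 3 * d / 16,
            d / 16,
        ]
        assert np.allclose(dist.pmf, expected, atol=1e-14)

    def test_merged_category_forms(self):
        d = 0.2
        dist = answer_pmf(4, d, "merge_top_bottom")
        assert dist.categories == (0, 1, 2, 3, 4)
        assert dist.pmf[0] == pytest.approx(1 / 16, abs=1e-14)
        assert np.allclose(
            dist.pmf[1:],
            [1 / 4 - 3 * d / 16, 3 / 8 - d / 8, 1 / 4 + d / 8, 1 / 16 + 3 * d / 16],
            atol=1e-14,
        )

    def test_any_other_category_forms(self):
        """Spreading d/16 uniformly gives +d/80 per category; category 3 is
        1/4 + 11d/80 (a uniform redistribution can only add mass)."""
        d = 0.2
        dist = answer_pmf(4, d, "any_other")
        expected = [
            1 / 16 - d / 20,
            1 / 4 - 7 * d / 40,
            3 / 8 - 9 * d / 80,
            1 / 4 + 11 * d / 80,
            1 / 16 + d / 5,
        ]
        assert np.allclose(dist.pmf, expected, atol=1e-14)


class TestEnumerationOracle:
    @pytest.mark.parametrize("scenario", ["honest", "merge_top_bottom", "any_other"])
    @pytest.mark.parametrize("m", [1, 2, 3, 4, 5, 6])
    def test_matches_exhaustive_enumeration(self, m, scenario):
        for d in np.linspace(0.0, 1.0, 6):
            dist = answer_pmf(m, d, scenario)
            oracle = enumerated_pmf(m, d, scenario)
            assert np.allclose(dist.pmf, oracle[: len(dist.pmf)], atol=1e-12)
            if scenario != "honest":
                assert oracle[m + 1] == 0.0

    def test_unequal_probabilities_against_enumeration(self):
        probs = (0.3, 0.55, 0.48)
        for scenario in ("honest", "merge_top_bottom", "any_other"):
            dist = answer_pmf(3, 0.4, scenario, probs=probs)
            assert np.allclose(
                dist.pmf, enumerated_pmf(3, 0.4, scenario, probs)[: len(dist.pmf)], atol=1e-12
            )


class TestInvariants:
    @pytest.mark.parametrize("scenario", ["honest", "merge_top_bottom", "any_other"])
    def test_normalisation_across_grid(self, scenario):
        for m in range(1, 9):
            for d in np.linspace(0.0, 1.0, 11):
                dist = answer_pmf(m, d, scenario)
                assert min(dist.pmf) >= -1e-15
                assert abs(sum(dist.pmf) - 1.0) < 1e-12

    def test_transforms_conserve_mass_groupwise(self):
        d, m = 0.35, 4
        honest = np.array(answer_pmf(m, d, "honest").pmf)
        merged = np.array(answer_pmf(m, d, "merge_top_bottom").pmf)
        spread = np.array(answer_pmf(m, d, "any_other").pmf)
        assert merged[0] == pytest.approx(honest[0] + honest[m + 1], abs=1e-14)
        assert np.allclose(merged[1:], honest[1:-1], atol=1e-14)
        assert np.allclose(spread, honest[:-1] + honest[m + 1] / (m + 1), atol=1e-14)

    def test_unknown_scenario_and_bad_d_rejected(self):
        with pytest.raises(DesignError, match="scenario"):
            answer_pmf(4, 0.2, "lie")
        with pytest.raises(DesignError, match="d"):
            answer_pmf(4, 1.2, "honest")


class TestExposure:
    def test_closed_form_cells(self):
        innocuous, sensitive = exposure_probabilities(4, 0.05)
        assert innocuous == pytest.approx(6.25, abs=1e-12)
        assert sensitive == pytest.approx(0.3125, abs=1e-12)
        assert exposure_probabilities(1, 0.5)[1] == pytest.approx(25.0, abs=1e-12)
        assert exposure_probabilities(8, 0.0)[1] == 0.0

    def test_table_is_exactly_the_closed_form(self):
        d_values = [0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5]
        table = exposure_table(range(1, 9), d_values)
        for i, m in enumerate(range(1, 9)):
            assert table.loc[i, "innocuous"] == pytest.approx(100 * 0.5**m, abs=1e-12)
            for d in d_values:
                assert table.loc[i, f"d={d:g}"] == pytest.approx(
                    100 * d * 0.5**m, abs=1e-12
                )

    def test_unequal_design_uses_product_of_probs(self):
        innocuous, _ = exposure_probabilities(2, 0.1, probs=(0.4, 0.6))
        assert innocuous == pytest.approx(24.0, abs=1e-12)


class TestDivergence:
    def test_ks_between_honest_and_mitigations_at_d_02(self):
        honest = answer_pmf(4, 0.2, "honest")
        assert compare_distributions(honest, answer_pmf(4, 0.2, "merge_top_bottom"))[
            "ks"
        ] == pytest.approx(0.0125, abs=1e-12)
        assert compare_distributions(honest, answer_pmf(4, 0.2, "any_other"))[
            "ks"
        ] == pytest.approx(0.0125, abs=1e-12)

    def test_self_comparison_is_zero(self):
        dist = answer_pmf(4, 0.3, "honest")
        res = compare_distributions(dist, dist)
        assert res["ks"] == 0.0
        assert res["rms"] == 0.0

    def test_mismatched_m_rejected(self):
        with pytest.raises(DesignError, match="m"):
            compare_distributions(answer_pmf(4, 0.2), answer_pmf(5, 0.2))

    def test_rms_is_root_mean_square_of_pmf_differences(self):
        a = answer_pmf(4, 0.2, "honest")
        b = answer_pmf(4, 0.2, "merge_top_bottom")
        pa, pb = a.full_support_pmf(), b.full_support_pmf()
        assert compare_distributions(a, b)["rms"] == pytest.approx(
            float(np.sqrt(np.mean((pa - pb) ** 2))), abs=1e-15
        )
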