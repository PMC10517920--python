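"""Hardy-Weinberg incidence arithmetic, exact Poisson CIs, rate tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from lsdincidence.acmg import AcmgClass
from lsdincidence.cohort import CohortVariant
from lsdincidence.incidence import (
    AggregationError,
    GeneIncidence,
    RiskMode,
    carrier_and_incidence,
    combined_incidence,
    compare_rates,
    disease_incidence,
    poisson_exact_ci,
    risk_allele_set,
    round_half_up,
)


def _variant(key_pos, ac, an=2990, gene="GAA"):
    return CohortVariant("17", key_pos, "A", "G", ac, an, gene, 0)


class TestCarrierAndIncidence:
    def test_pompe_worked_example(self):
        """q = 0.0065 gives an incidence of 4.23 per 100,000 (2 dp)."""
        carrier, incidence = carrier_and_incidence(0.0065)
        assert round_half_up(incidence * 100_000, 2) == 4.23
        assert carrier == pytest.approx(2 * 0.9935 * 0.0065)

    @pytest.mark.parametrize("q,expected", [(0.0, (0.0, 0.0)), (1.0, (0.0, 1.0))])
    def test_boundary_identities(self, q, expected):
        assert carrier_and_incidence(q) == expected

    def test_one_percent_allele(self):
        carrier, incidence = carrier_and_incidence(0.01)
        assert carrier == pytest.approx(0.0198)
        assert incidence == pytest.approx(1.0e-4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            carrier_and_incidence(1.2)

    @given(st.floats(0, 1, allow_nan=False))
    def test_hwe_identity(self, q):
        carrier, incidence = carrier_and_incidence(q)
        assert carrier + incidence + (1 - q) ** 2 == pytest.approx(1.0, abs=1e-12)


class TestRiskAlleleSet:
    CLASSES = {
        "17-100-A-G": AcmgClass.PATHOGENIC,
        "17-200-A-G": AcmgClass.VUS,
        "17-300-A-G": AcmgClass.BENIGN,
    }

    def _variants(self):
        # AFs: 0.003, 0.002, 0.04
        return [
            _variant(100, ac=9, an=3000),
            _variant(200, ac=6, an=3000),
            _variant(300, ac=120, an=3000),
        ]

    def test_conservative_and_extended_sums(self):
        cons = risk_allele_set("GAA", self.CLASSES, self._variants(), "conservative")
        ext = risk_allele_set("GAA", self.CLASSES, self._variants(), "extended")
        assert cons.q == pytest.approx(0.003)
        assert ext.q == pytest.approx(0.005)
        assert cons.variant_keys <= ext.variant_keys
        assert cons.Q + cons.q == pytest.approx(1.0)

    def test_benign_never_included_and_empty_gene(self):
        ext = risk_allele_set("GAA", self.CLASSES, self._variants(), "extended")
        assert "17-300-A-G" not in ext.variant_keys
        empty = risk_allele_set("IDUA", self.CLASSES, self._variants(), "extended")
        assert empty.q == 0.0
        carrier, incidence = carrier_and_incidence(empty.q)
        assert (carrier, incidence) == (0.0, 0.0)

    def test_q_above_one_rejected(self):
        classes = {"17-100-A-G": AcmgClass.PATHOGENIC, "17-200-A-G": AcmgClass.PATHOGENIC}
        bad = [_variant(100, ac=1800, an=3000), _variant(200, ac=1800, an=3000)]
        with pytest.raises(AggregationError):
            risk_allele_set("GAA", classes, bad, "conservative")


class TestPoissonExactCI:
    @pytest.mark.parametrize(
        "count,expected",
        [
            (13, (6.92, 22.23)),
            (94, (75.96, 115.03)),
        ],
    )
    def test_published_intervals(self, count, expected):
        lo, hi = poisson_exact_ci(count)
        assert (round_half_up(lo, 2), round_half_up(hi, 2)) == expected

    def test_zero_count(self):
        lo, hi = poisson_exact_ci(0)
        assert lo == 0.0
        assert round_half_up(hi, 2) == 3.69  # half the 0.975 chi2 quantile, 2 df

    def test_chi_square_equivalence_and_denominator(self):
        lo, hi = poisson_exact_ci(13, denominator=100_000)
        assert lo == pytest.approx(stats.chi2.ppf(0.025, 26) / 2 / 100_000)
        assert hi == pytest.approx(stats.chi2.ppf(0.975, 28) / 2 / 100_000)

    def test_continuous_count_brackets_point(self):
        lo, hi = poisson_exact_ci(2.21)
        assert 0 < lo < 2.21 < hi

    def test_level_validation(self):
        with pytest.raises(ValueError):
            poisson_exact_ci(5, level=1.5)


class TestCompareRates:
    def test_equal_rates_p_one(self):
        assert compare_rates(5, 1000, 5, 1000).p_value == pytest.approx(1.0)

    def test_extreme_imbalance_significant(self):
        # K=10 split 0:10 at p0=0.5 -> exact two-sided p = 2/1024
        cmp = compare_rates(0, 1000, 10, 1000)
        assert cmp.p_value == pytest.approx(2 / 1024)
        assert cmp.p_value < 0.01

    def test_symmetry_under_swap(self):
        a = compare_rates(3, 1495, 11, 994_975)
        b = compare_rates(11, 994_975, 3, 1495)
        assert a.p_value == pytest.approx(b.p_value)

    def test_both_zero_degenerate(self):
        cmp = compare_rates(0, 100, 0, 200)
        assert cmp.p_value == 1.0 and cmp.degenerate

    def test_normal_approximation_agrees_at_large_counts(self):
        exact = compare_rates(500, 10_000, 560, 10_000).p_value
        approx = compare_rates(500, 10_000, 560, 10_000, method="normal").p_value
        assert exact == pytest.approx(approx, rel=0.15)


class TestDiseaseAndCombined:
    def test_combined_additivity(self):
        reports = [
            GeneIncidence(f"D{i}", frozenset({f"G{i}"}), RiskMode.CONSERVATIVE,
                          0.01, 0.0198, 1e-4, 10.0, (0.0, 1.0))
            for i in range(2)
        ]
        assert combined_incidence(reports) == 20.0
        assert combined_incidence([]) == 0.0

    def test_duplicate_disease_rejected(self):
        rep = GeneIncidence("D", frozenset({"G"}), RiskMode.CONSERVATIVE,
                            0.01, 0.0198, 1e-4, 10.0, (0.0, 1.0))
        with pytest.raises(AggregationError):
            combined_incidence([rep, rep])

    def test_disease_pools_genes_and_brackets_ci(self):
        classes = {"17-100-A-G": AcmgClass.PATHOGENIC, "1-100-A-G": AcmgClass.PATHOGENIC}
        variants = [
            _variant(100, ac=9, an=3000, gene="GA"),
            CohortVariant("1", 100, "A", "G", 6, 3000, "GB", 0),
        ]
        sets = [
            risk_allele_set("GA", classes, variants, "conservative"),
            risk_allele_set("GB", classes, variants, "conservative"),
        ]
        rep = disease_incidence("Two-gene disease", sets)
        assert rep.q == pytest.approx(0.005)
        assert rep.incidence == pytest.approx(2.5e-5)
        assert rep.ci95_per_100k[0] <= rep.incidence_per_100k <= rep.ci95_per_100k[1]
        # HWE identity
        assert rep.carrier_rate + rep.incidence + (1 - rep.q) ** 2 == pytest.approx(1.0)


class TestCoverage:
    @pytest.mark.parametrize("lam", [2, 13, 94])
    def test_exact_ci_covers_at_least_nominal(self, lam):
        """10,000 Poisson draws per rate: the Garwood interval covers the
        true rate at >= 95% (exact intervals are conservative)."""
        rng = np.random.default_rng(20_240 + lam)
        draws = rng.poisson(lam, size=10_000)
        ks = np.arange(draws.max() + 1)
        lows = np.where(ks == 0, 0.0, stats.gamma.ppf(0.025, np.maximum(ks, 1)))
        highs = stats.gamma.ppf(0.975, ks + 1)
        covered = (lows[draws] <= lam) & (lam <= highs[draws])
        assert covered.mean() >= 0.95

    def test_exact_rate_test_type_i_error_conservative(self):
        """Under equal rates the exact conditional test rejects at < 5%."""
        rng = np.random.default_rng(7)
        n_rej = 0
        reps = 2000
        for _ in range(reps):
            a = rng.poisson(6)
            b = rng.poisson(6)
            if compare_rates(a, 1.0, b, 1.0).p_value < 0.05:
                n_rej += 1
        assert n_rej / reps <= 0.05


def test_round_half_up_behaviour():
    assert round_half_up(4.225, 2) == 4.23
    assert round_half_up(2.675, 2) == 2.68  # decimal, not binary-float, ties
    assert round_half_up(1.0, 2) == 1.0
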