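"""2x2 table reconstruction, odds ratios, CIs and the exact test."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from varburden.enrichment import (
    EnrichmentResult,
    TwoByTwo,
    build_table,
    classify_enrichment,
    enrich_variants,
    exact_p,
    or_ci,
    sample_or,
)
from tests.conftest import make_variant

positive_cells = st.tuples(*[st.integers(1, 500)] * 4).map(lambda t: TwoByTwo(*t))


def _nfe_afr_variant():
    from varburden.datamodel import PopFrequency

    v = make_variant(NFE=1.34e-3)
    v.per_pop["AFR"] = PopFrequency(an=16_256, af=1.48e-4)
    return v


class TestBuildTable:
    def test_af_reconstruction_keeps_real_valued_counts(self):
        t = build_table(_nfe_afr_variant(), "NFE", "AFR")
        assert t.a == pytest.approx(1.34e-3 * 113_770)
        assert t.a + t.b == 113_770

    def test_nearest_rounding_matches_hand_computation(self):
        t = build_table(_nfe_afr_variant(), "NFE", "AFR", rounding="nearest")
        assert (t.a, t.b, t.c, t.d) == (152, 113_618, 2, 16_254)

    def test_zero_af_gives_empty_alt_cell(self):
        v = make_variant(NFE=0.0, AFR=(4, 16_256))
        t = build_table(v, "NFE", "AFR")
        assert (t.a, t.b) == (0.0, 113_770)

    def test_cohort_side_uses_cohort_counts(self):
        v = make_variant(cohort=(5, 200), NFE=1e-3)
        t = build_table(v, "FMD", "NFE")
        assert (t.a, t.b) == (5, 195)

    def test_absent_population_falls_back_to_panel_allele_number(self):
        v = make_variant(NFE=1e-3)
        from varburden.populations import GNOMAD_V21_EXOMES

        t = build_table(v, "NFE", "EAS", panel=GNOMAD_V21_EXOMES)
        assert (t.c, t.d) == (0.0, 18_394)


class TestSampleOr:
    def test_printed_table2_row_reproduced_from_afs(self):
        v = _nfe_afr_variant()
        assert sample_or(build_table(v, "NFE", "AFR")) == pytest.approx(9.07, rel=0.01)

    def test_equal_odds_give_unity(self):
        assert sample_or(TwoByTwo(7, 13, 7, 13)) == 1.0

    def test_all_ones_with_and_without_haldane(self):
        t = TwoByTwo(1, 1, 1, 1)
        assert sample_or(t) == 1.0
        assert sample_or(t, "haldane") == 1.0

    def test_zero_policies(self):
        t = TwoByTwo(3, 97, 0, 100)
        assert sample_or(t, "none") == math.inf
        assert sample_or(TwoByTwo(0, 100, 3, 97), "none") == 0.0
        assert sample_or(t, "haldane") == pytest.approx(
            (3.5 * 100.5) / (97.5 * 0.5)
        )

    @given(positive_cells)
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry(self, t):
        forward = sample_or(t)
        backward = sample_or(TwoByTwo(t.c, t.d, t.a, t.b))
        assert forward * backward == pytest.approx(1.0)

    @given(positive_cells, st.integers(2, 50))
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_cellwise_scaling(self, t, k):
        scaled = TwoByTwo(t.a * k, t.b * k, t.c * k, t.d * k)
        assert sample_or(scaled) == pytest.approx(sample_or(t))


class TestOrCi:
    def test_woolf_interval_contains_point_estimate(self):
        t = TwoByTwo(152, 113_618, 2, 16_254)
        low, high = or_ci(t)
        assert low < sample_or(t) < high

    def test_woolf_matches_brute_force_log_variance(self):
        t = TwoByTwo(20, 80, 10, 90)
        low, high = or_ci(t, level=0.95)
        se = math.sqrt(1 / 20 + 1 / 80 + 1 / 10 + 1 / 90)
        z = stats.norm.ppf(0.975)
        point = (20 * 90) / (80 * 10)
        assert low == pytest.approx(point * math.exp(-z * se))
        assert high == pytest.approx(point * math.exp(z * se))

    def test_symmetric_about_one_for_equal_cells(self):
        low, high = or_ci(TwoByTwo(25, 25, 25, 25))
        assert math.log(low) == pytest.approx(-math.log(high))

    def test_exact_interval_with_zero_alt_in_pop2(self):
        low, high = or_ci(TwoByTwo(5, 95, 0, 100), method="exact")
        assert 0 < low < math.inf
        assert math.isinf(high)

    def test_degenerate_table_is_flagged_not_raised(self):
        low, high = or_ci(TwoByTwo(0, 50, 0, 50))
        assert math.isnan(low) and math.isnan(high)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            or_ci(TwoByTwo(1, 1, 1, 1), level=1.0)


class TestExactP:
    def test_large_sparse_table_is_significant(self):
        assert exact_p(TwoByTwo(152, 113_618, 2, 16_254)) < 0.05

    def test_matched_odds_large_counts_near_one(self):
        assert exact_p(TwoByTwo(50, 450, 100, 900)) > 0.9

    def test_agrees_with_scipy_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 30, size=4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            ours = exact_p(TwoByTwo(int(a), int(b), int(c), int(d)))
            ref = stats.fisher_exact([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(ref, rel=1e-7)

    def test_small_margin_tables_match_enumeration(self):
        for a in range(0, 6):
            for c in range(0, 6):
                t = TwoByTwo(a, 6 - a, c, 6 - c)
                assert exact_p(t) == pytest.approx(
                    _enumerate_p(a, 6 - a, c, 6 - c), rel=1e-9
                )


def _enumerate_p(a, b, c, d):
    """Independent oracle: direct enumeration over fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = math.comb(r1 + r2, c1)
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    probs = {k: math.comb(r1, k) * math.comb(r2, c1 - k) / denom for k in support}
    return sum(p for p in probs.values() if p <= probs[a] * (1 + 1e-9))


class TestClassifyEnrichment:
    def _result(self, or_point, p):
        return EnrichmentResult("v", "NFE", "AFR", or_point, 0, 0, p, "woolf")

    def test_printed_enriched_row(self):
        (r,) = classify_enrichment([self._result(9.07, 4.26e-3)])
        assert r.enriched and not r.depleted

    def test_printed_non_significant_row(self):
        (r,) = classify_enrichment([self._result(0.71, 7.50e-2)])
        assert not r.enriched and not r.depleted

    def test_boundary_requires_p_strictly_below_alpha(self):
        (r,) = classify_enrichment([self._result(1.0, 1.0)])
        assert not r.enriched

    def test_depletion_flag(self):
        (r,) = classify_enrichment([self._result(0.25, 1e-5)])
        assert r.depleted and not r.enriched


class TestEnrichVariants:
    def test_frame_has_one_row_per_variant_pair(self, fmd_cohort):
        pairs = [("NFE", p) for p in ("AFR", "EAS", "SAS", "AMR")]
        df = enrich_variants(fmd_cohort, pairs)
        assert len(df) == 13 * 4
        assert set(df.columns) >= {
            "variant", "pop1", "pop2", "or_point", "ci_low", "ci_high",
            "p_value", "enriched", "depleted",
        }

    def test_published_nfe_enriched_variants_are_flagged(self, fmd_cohort):
        # The seven cohort variants with a printed significant NFE-side OR
        # must be flagged enriched in at least one comparison, and the
        # NFE-private singleton (g.17611118, absent elsewhere) must never
        # reach significance despite its infinite OR.
        pairs = [("NFE", p) for p in ("AFR", "EAS", "SAS", "AMR")]
        df = enrich_variants(fmd_cohort, pairs)
        flagged = set(df[df["enriched"]]["variant"])
        for pos in (17_553_211, 17_599_671, 17_606_001, 17_610_645,
                    17_612_217, 17_635_125, 17_642_200):
            assert any(str(pos) in v for v in flagged), pos
        private = df[df["variant"].str.contains("17611118")]
        assert (private["p_value"] >= 0.05).all()

    def test_bh_adjustment_adds_monotone_q_column(self, fmd_cohort):
        df = enrich_variants(fmd_cohort, [("NFE", "AFR")], bh_adjust=True)
        assert (df["q_value"] >= df["p_value"] - 1e-12).all()


class TestPrintedOddsRatios:
    """Every non-empty OR cell of the published cross-population tables.

    Expected values are the printed ORs; tolerance is 2% relative or half
    of the last printed digit, whichever is wider (ORs printed at two
    decimals near zero are dominated by print rounding).
    """

    CELLS = [
        # (pos, pop2, printed OR, printed decimals)
        (17_553_211, "AFR", 9.07, 2), (17_553_211, "SAS", 15.11, 2),
        (17_553_211, "AMR", 0.71, 2),
        (17_599_671, "AFR", 6.33, 2), (17_599_671, "SAS", 7.86, 2),
        (17_599_671, "AMR", 3.91, 2),
        (17_606_001, "AFR", 9.24, 2), (17_606_001, "SAS", 8.39, 2),
        (17_606_001, "AMR", 1.86, 2),
        (17_610_645, "AFR", 24.41, 2), (17_610_645, "AMR", 3.54, 2),
        (17_612_217, "AFR", 10.89, 2), (17_612_217, "EAS", 4.32, 2),
        (17_612_217, "SAS", 7.22, 2), (17_612_217, "AMR", 2.31, 2),
        (17_635_125, "AFR", 31.53, 2), (17_635_125, "SAS", 1.52, 2),
        (17_635_125, "AMR", 3.00, 2),
        (17_642_200, "EAS", 31.26, 2), (17_642_200, "SAS", 1.10, 2),
        (17_642_200, "AMR", 1.13, 2),
        (17_557_227, "AFR", 0.07, 2), (17_557_227, "SAS", 3.13, 2),
        (17_557_227, "AMR", 0.32, 2),
        (17_611_374, "AFR", 0.28, 2), (17_611_374, "EAS", 13.25, 2),
        (17_611_374, "SAS", 0.26, 2), (17_611_374, "AMR", 0.25, 2),
        (17_638_480, "AFR", 0.01, 2), (17_638_480, "AMR", 0.21, 2),
        (17_640_936, "AFR", 0.02, 2), (17_640_936, "EAS", 2.59, 2),
        (17_640_936, "SAS", 2.70, 2), (17_640_936, "AMR", 0.26, 2),
    ]

    @pytest.mark.parametrize("pos,pop2,printed,decimals", CELLS)
    def test_recomputed_or_matches_printed(self, fmd_cohort, pos, pop2,
                                           printed, decimals):
        record = next(r for r in fmd_cohort if r.pos == pos)
        value = sample_or(build_table(record, "NFE", pop2))
        tolerance = max(0.02 * printed, 0.5 * 10 ** (-decimals))
        assert value == pytest.approx(printed, abs=tolerance)
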