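"""Sliding-window density, thresholds, region calling and similarity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varburden.datamodel import single_interval_gene
from varburden.density import (
    DensityProfile,
    ExpectedCounts,
    RegionSet,
    an_share_scales,
    annotate_variant_region,
    call_regions,
    density_profile,
    population_threshold,
    profile_similarity,
)
from tests.conftest import make_variant


def variant_at(cds_pos, **kwargs):
    kwargs.setdefault("NFE", (3, 100))
    return make_variant(pos=cds_pos, cds_pos=cds_pos, **kwargs)


@pytest.fixture
def kilobase_gene():
    return single_interval_gene("G", 1000)


class TestDensityProfile:
    def test_single_interior_variant_spreads_over_the_window(self, kilobase_gene):
        profile = density_profile([variant_at(500)], kilobase_gene, "NFE")
        dens = profile.density
        assert dens[399] == dens[499] == dens[599] == pytest.approx(1 / 201)
        assert dens[398] == 0.0 and dens[600] == 0.0

    def test_no_variants_gives_zero_everywhere(self, kilobase_gene):
        profile = density_profile([], kilobase_gene, "NFE")
        assert not profile.density.any()

    def test_terminal_window_is_clipped_and_rescaled(self, kilobase_gene):
        profile = density_profile([variant_at(1)], kilobase_gene, "NFE")
        assert profile.density[0] == pytest.approx(1 / 101)

    def test_only_sites_carried_in_the_population_count(self, kilobase_gene):
        absent = variant_at(500, NFE=(0, 100))
        profile = density_profile([absent], kilobase_gene, "NFE")
        assert not profile.density.any()

    def test_duplicate_sites_count_once(self, kilobase_gene):
        profile = density_profile(
            [variant_at(500), variant_at(500)], kilobase_gene, "NFE"
        )
        assert profile.density[499] == pytest.approx(1 / 201)

    def test_missing_cds_pos_lists_offenders(self, kilobase_gene):
        bad = make_variant(pos=77, NFE=(3, 100))
        with pytest.raises(ValueError, match="cds_pos"):
            density_profile([bad], kilobase_gene, "NFE")

    def test_window_mass_conservation_for_interior_variants(self, kilobase_gene):
        # each interior variant contributes to exactly 2h+1 positions
        variants = [variant_at(p) for p in (300, 500, 700)]
        profile = density_profile(variants, kilobase_gene, "NFE")
        lo = np.maximum(np.arange(1, 1001) - 100, 1)
        hi = np.minimum(np.arange(1, 1001) + 100, 1000)
        mass = float((profile.density * (hi - lo + 1)).sum())
        assert mass == pytest.approx(201 * len(variants))

    def test_step_parameter_holds_values_between_evaluations(self, kilobase_gene):
        fine = density_profile([variant_at(500)], kilobase_gene, "NFE", step=1)
        coarse = density_profile([variant_at(500)], kilobase_gene, "NFE", step=10)
        assert len(coarse.density) == 1000
        assert coarse.density[0] == fine.density[0]


class TestThreshold:
    def test_direct_proportion_arithmetic(self):
        gene = single_interval_gene("G", 8_778)
        expected = ExpectedCounts(overall=400, scale={"NFE": 0.5})
        assert population_threshold(expected, gene, "NFE") == pytest.approx(
            200 / 8_778
        )

    def test_global_scale_is_identity(self):
        gene = single_interval_gene("G", 1_000)
        expected = ExpectedCounts(overall=400, scale={})
        assert population_threshold(expected, gene, "GLOBAL") == pytest.approx(0.4)

    def test_zero_expected_count_rejected(self):
        with pytest.raises(ValueError):
            ExpectedCounts(overall=0.0)

    def test_missing_scale_is_an_error(self):
        with pytest.raises(ValueError, match="scale"):
            ExpectedCounts(overall=10, scale={}).expected("NFE")

    def test_an_share_scales_sum_to_within_the_global_share(self):
        scales = an_share_scales()
        assert scales["NFE"] == pytest.approx(113_770 / 251_496)
        assert 0 < sum(scales.values()) <= 1.0


class TestCallRegions:
    def test_uniformly_low_density_is_one_ldr(self, kilobase_gene):
        profile = density_profile([], kilobase_gene, "NFE").with_threshold(0.01)
        regions = call_regions(profile)
        assert regions.regions == ((0, 1000, "LDR"),)

    def test_alternating_labels_make_unit_regions(self):
        density = np.tile([0.0, 1.0], 50)
        profile = DensityProfile("NFE", 100, 100, 1, density, threshold=0.5)
        regions = call_regions(profile)
        assert len(regions.regions) == 100
        assert all(e - s == 1 for s, e, _ in regions.regions)

    def test_caller_matches_per_position_brute_force(self, rng):
        for _ in range(20):
            density = rng.random(rng.integers(5, 400))
            profile = DensityProfile("X", len(density), 100, 1, density,
                                     threshold=0.5)
            regions = call_regions(profile)
            assert (regions.label_array() == profile.labels).all()

    def test_raising_threshold_never_shrinks_ldr_length(self, rng):
        density = rng.random(500)
        lengths = []
        for threshold in (0.1, 0.3, 0.5, 0.9):
            profile = DensityProfile("X", 500, 100, 1, density, threshold)
            lengths.append(call_regions(profile).ldr_length)
        assert lengths == sorted(lengths)

    def test_partition_is_validated(self):
        with pytest.raises(ValueError):
            RegionSet("X", 10, ((0, 5, "LDR"), (6, 10, "HDR")))
        with pytest.raises(ValueError):
            RegionSet("X", 10, ((0, 5, "LDR"), (5, 10, "LDR")))


class TestAnnotate:
    def test_label_of_containing_region(self):
        regions = RegionSet("X", 1000, ((0, 400, "LDR"), (400, 1000, "HDR")))
        assert annotate_variant_region(regions, variant_at(400)) == "LDR"
        assert annotate_variant_region(regions, variant_at(401)) == "HDR"

    def test_single_ldr_region_labels_everything_ldr(self):
        regions = RegionSet("X", 1000, ((0, 1000, "LDR"),))
        assert annotate_variant_region(regions, variant_at(7)) == "LDR"

    def test_position_outside_cds_rejected(self):
        regions = RegionSet("X", 1000, ((0, 1000, "LDR"),))
        with pytest.raises(ValueError, match="outside"):
            annotate_variant_region(regions, variant_at(1001))


class TestSimilarity:
    def test_identical_region_sets_score_100(self):
        a = RegionSet("X", 1000, ((0, 400, "LDR"), (400, 1000, "HDR")))
        assert profile_similarity(a, a) == 100.0

    def test_complementary_labelings_score_0(self):
        a = RegionSet("X", 1000, ((0, 1000, "LDR"),))
        b = RegionSet("X", 1000, ((0, 1000, "HDR"),))
        assert profile_similarity(a, b) == 0.0

    def test_hand_computed_three_quarters_overlap(self):
        a = RegionSet("X", 1000, ((0, 500, "LDR"), (500, 1000, "HDR")))
        b = RegionSet("X", 1000, ((0, 250, "LDR"), (250, 1000, "HDR")))
        assert profile_similarity(a, b) == 75.0

    @given(st.integers(1, 999), st.integers(1, 999))
    @settings(max_examples=50, deadline=None)
    def test_symmetric(self, cut_a, cut_b):
        a = RegionSet("X", 1000, ((0, cut_a, "LDR"), (cut_a, 1000, "HDR")))
        b = RegionSet("X", 1000, ((0, cut_b, "LDR"), (cut_b, 1000, "HDR")))
        assert profile_similarity(a, b) == profile_similarity(b, a)

    def test_mismatched_lengths_rejected(self):
        a = RegionSet("X", 10, ((0, 10, "LDR"),))
        b = RegionSet("X", 20, ((0, 20, "LDR"),))
        with pytest.raises(ValueError, match="lengths differ"):
            profile_similarity(a, b)


class TestPlantedLdrRecovery:
    def test_planted_segment_recovered_with_high_jaccard(self):
        # One 1,500-bp segment thinned to 10% intensity among ~2,000
        # variants; threshold midway between background and thinned
        # density.  A single seed here; the multi-seed median is exercised
        # in the acceptance suite.
        from varburden.simulate import SimulationConfig, simulate_frequency_table

        cfg = SimulationConfig(seed=3, n_variants=2000,
                               ldr_segments=(((3000, 4500), 0.1),))
        records, _ = simulate_frequency_table(cfg)
        gene = cfg.gene
        base = cfg.n_variants / gene.cds_length
        profile = density_profile(records, gene, "GLOBAL").with_threshold(base / 2)
        called = call_regions(profile).label_array() == "LDR"
        planted = np.zeros(gene.cds_length, dtype=bool)
        planted[3000:4500] = True
        jaccard = (called & planted).sum() / (called | planted).sum()
        assert jaccard >= 0.8
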