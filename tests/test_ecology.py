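"""Trait banding, group scoring and the nested ecological risk to resource."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cfsr._rounding import round_half_up
from cfsr.ecology import (
    FamilyTraits,
    classify_trait_level,
    community_resource_component,
    ecological_risk_to_resource,
    group_component,
    group_indicator_score,
    level_to_score,
    score_groups,
)
from cfsr.reference import (
    ECOLOGICAL_RISK,
    GROUP_COMPONENT_AVERAGES,
    GROUP_TRAIT_SCORES,
    RESOURCE_COMPONENTS,
    RESOURCE_VULNERABILITY,
)


def _family(**overrides) -> FamilyTraits:
    base = dict(
        family="Testidae", group="demersal", depth_habitat="below_50m",
        feeding_class="higher_predator", age_at_maturity=3.0,
        trophic_level=3.0, latitudinal_range=50.0, vulnerability_score=50.0,
    )
    base.update(overrides)
    return FamilyTraits(**base)


# interiors and boundaries of every band; boundaries fall in moderate
BAND_CASES = [
    ("EE1", "below_50m", "low"),
    ("EE1", "above_50m", "moderate"),
    ("EE1", "reef_or_pelagic_all_stages", "high"),
    ("EE2", "higher_predator", "low"),
    ("EE2", "macro_invertebrate_feeder", "moderate"),
    ("EE2", "filter_feeder", "high"),
    ("ES1", 1.5, "low"), ("ES1", 2.0, "moderate"), ("ES1", 5.0, "moderate"),
    ("ES1", 10.0, "moderate"), ("ES1", 10.5, "high"),
    ("ES2", 1.8, "low"), ("ES2", 2.0, "moderate"), ("ES2", 3.0, "moderate"),
    ("ES2", 4.0, "moderate"), ("ES2", 4.5, "high"),
    ("EA1", 30.0, "low"), ("EA1", 45.0, "moderate"), ("EA1", 60.0, "moderate"),
    ("EA1", 90.0, "moderate"), ("EA1", 120.0, "high"),
    ("EA2", 80.0, "low"), ("EA2", 66.0, "moderate"), ("EA2", 50.0, "moderate"),
    ("EA2", 33.0, "moderate"), ("EA2", 20.0, "high"),
]


@pytest.mark.parametrize("trait,value,expected", BAND_CASES)
def test_trait_band_assignment(trait, value, expected):
    assert classify_trait_level(trait, value) == expected


def test_unknown_trait_and_out_of_range_values_rejected():
    with pytest.raises(ValueError):
        classify_trait_level("ZZ9", 1.0)
    with pytest.raises(ValueError):
        classify_trait_level("ES1", -1.0)
    with pytest.raises(ValueError):
        classify_trait_level("EA2", 150.0)


def test_level_scores_are_the_three_point_scale():
    assert [level_to_score(lv) for lv in ("low", "moderate", "high")] == [0.0, 0.5, 1.0]
    with pytest.raises(ValueError):
        level_to_score("extreme")


class TestGroupScores:
    def test_mixed_levels_average(self):
        fams = [_family(age_at_maturity=1.5), _family(age_at_maturity=12.0)]
        assert group_indicator_score(fams, "ES1") == pytest.approx(0.5)

    def test_single_high_family_scores_one(self):
        assert group_indicator_score([_family(trophic_level=4.5)], "ES2") == 1.0

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            group_indicator_score([], "ES1")

    def test_fixture_reproduces_every_published_trait_cell(self, trait_fixture):
        scores = score_groups(trait_fixture)
        for trait, expected in GROUP_TRAIT_SCORES.items():
            if trait.startswith("EH"):
                continue  # climate-side, not trait-based
            for group, value in expected.items():
                assert round_half_up(scores.loc[group, trait], 3) == value, (
                    trait, group)

    def test_component_averages_of_rounded_cells_match_published(self, trait_fixture):
        scores = score_groups(trait_fixture)
        pairs = {"RE": ("EE1", "EE2"), "RS": ("ES1", "ES2"), "RAC": ("EA1", "EA2")}
        for comp, (a, b) in pairs.items():
            for group, expected in GROUP_COMPONENT_AVERAGES[comp].items():
                got = round_half_up(
                    (round_half_up(scores.loc[group, a], 3)
                     + round_half_up(scores.loc[group, b], 3)) / 2.0, 3)
                assert got == expected, (comp, group)

    def test_group_component_is_the_mean(self):
        assert group_component(1.000, 0.500) == pytest.approx(0.750)
        assert group_component(0.500, 0.750) == pytest.approx(0.625)
        assert group_component(0.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            group_component(1.2, 0.0)


class TestCommunityWeighting:
    RS = {"coral_reef_fish": 0.438, "small_pelagic": 0.250, "large_pelagic": 0.584,
          "cephalopods": 0.375, "demersal": 0.500}

    def test_degenerate_consumption_returns_that_groups_score(self):
        assert community_resource_component(
            self.RS, {"small_pelagic": 1.0}) == pytest.approx(0.250)

    def test_weighted_mean(self):
        re = {"coral_reef_fish": 0.750, "demersal": 0.000}
        got = community_resource_component(
            re, {"coral_reef_fish": 0.5, "demersal": 0.5})
        assert got == pytest.approx(0.375)

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            community_resource_component(self.RS, {"demersal": 0.9})

    def test_consumed_group_without_score_is_an_error(self):
        with pytest.raises(ValueError, match="seagrass"):
            community_resource_component(
                {"demersal": 0.5}, {"demersal": 0.5, "seagrass": 0.5})


class TestEcologicalRisk:
    @pytest.mark.parametrize("community", ["Mafia", "Pemba", "Tanga", "Unguja"])
    def test_published_components_compose_to_published_err(self, community):
        v, err = ecological_risk_to_resource(
            RESOURCE_COMPONENTS["RH"][community],
            RESOURCE_COMPONENTS["RE"][community],
            RESOURCE_COMPONENTS["RS"][community],
            RESOURCE_COMPONENTS["RAC"][community],
        )
        if community in ("Mafia", "Pemba"):
            # Tanga/Unguja vulnerabilities were printed from unrounded
            # intermediates (0.4005/0.4085 round the other way)
            assert round_half_up(v, 3) == RESOURCE_VULNERABILITY[community]
        assert round_half_up(err, 3) == ECOLOGICAL_RISK[community]

    def test_no_risk_corner(self):
        v, err = ecological_risk_to_resource(0, 0, 0, 1)
        assert v == 0.0 and err == 0.0

    def test_literal_mode_can_leave_the_unit_interval(self):
        _, err = ecological_risk_to_resource(1, 1, 1, 0, mode="literal")
        assert err == pytest.approx(2.0)

    def test_monotone_over_grid(self):
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        for rh, re, rs, rac in itertools.product(grid, repeat=4):
            _, err = ecological_risk_to_resource(rh, re, rs, rac)
            assert 0.0 <= err <= 1.0
            eps = 0.25
            if rh + eps <= 1:
                assert ecological_risk_to_resource(rh + eps, re, rs, rac)[1] >= err
            if rs + eps <= 1:
                assert ecological_risk_to_resource(rh, re, rs + eps, rac)[1] >= err
            if rac + eps <= 1:
                assert ecological_risk_to_resource(rh, re, rs, rac + eps)[1] <= err

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_default_mode_stays_in_unit_interval(self, rh, re, rs, rac):
        v, err = ecological_risk_to_resource(rh, re, rs, rac)
        assert 0.0 <= v <= 1.0
        assert 0.0 <= err <= 1.0


def test_family_trait_invariants_enforced():
    with pytest.raises(ValueError):
        _family(group="seagrass")
    with pytest.raises(ValueError):
        _family(age_at_maturity=0.0)
    with pytest.raises(ValueError):
        _family(trophic_level=6.0)
    with pytest.raises(ValueError):
        _family(vulnerability_score=120.0)
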