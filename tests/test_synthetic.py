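"""Synthetic-data generators: determinism, parameter recovery, fixture targets."""

import numpy as np
import pandas as pd
import pytest

from cfsr._rounding import round_half_up
from cfsr.climate import index_of_variability
from cfsr.ecology import score_groups
from cfsr.reference import GROUP_TRAIT_SCORES
from cfsr.registry import default_registry
from cfsr.social import community_question_score
from cfsr.survey import validate_survey
from cfsr.synthetic import (
    CommunityScenario,
    default_scenarios,
    generate_climate_series,
    generate_survey,
    generate_trait_fixture,
)


class TestGenerateSurvey:
    def test_default_scenarios_match_the_study_design(self, demo_survey):
        counts = demo_survey["community"].value_counts()
        assert counts["Mafia"] == 90
        assert counts["Pemba"] == 49
        assert counts["Tanga"] == 52
        assert counts["Unguja"] == 102
        assert len(demo_survey) == 293

    def test_same_seed_gives_identical_tables(self, registry):
        a = generate_survey(default_scenarios(), seed=5, registry=registry)
        b = generate_survey(default_scenarios(), seed=5, registry=registry)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self, registry):
        a = generate_survey(default_scenarios(), seed=5, registry=registry)
        b = generate_survey(default_scenarios(), seed=6, registry=registry)
        assert not a.equals(b)

    def test_degenerate_distribution_gives_certain_score(self, registry):
        scens = [CommunityScenario(name="Mafia", n=50,
                                   distributions={"shoreline_eroded": 1.0})]
        scens += [CommunityScenario(name=c, n=2)
                  for c in ("Pemba", "Tanga", "Unguja")]
        raw = generate_survey(scens, seed=0, registry=registry)
        table, _ = validate_survey(raw, registry)
        q = registry.question("shoreline_eroded")[1]
        score, n = community_question_score(table, q, "Mafia")
        assert score == 1.0 and n == 50

    def test_invalid_distribution_parameters_rejected(self, registry):
        scen = CommunityScenario(name="Mafia", n=5,
                                 distributions={"storm_damage": (0.5, 0.5, 0.5, 0.5)})
        with pytest.raises(ValueError, match="Likert"):
            generate_survey([scen], seed=0, registry=registry)

    def test_dependence_pair_respects_the_invariant(self, demo_survey):
        dwf = demo_survey["days_fish_protein"].astype(int)
        tdwp = demo_survey["days_any_protein"].astype(int)
        assert (dwf <= tdwp).all()
        assert (tdwp <= 7).all() and (tdwp >= 1).all()


class TestGenerateClimate:
    def test_null_shift_recovered_near_zero(self):
        ivs = [
            index_of_variability(
                generate_climate_series(252, 27.0, 0.0, 0.5, seed=s),
                (2001, 2011), (2011, 2021)).iv
            for s in range(100)
        ]
        se = np.std(ivs, ddof=1) / np.sqrt(len(ivs))
        assert abs(np.mean(ivs)) <= 3 * se

    def test_configured_shift_recovered(self):
        """Monte-Carlo over 100 seeds: mean IV within 3 SE of the 2-sigma shift."""
        shift = 2.0
        ivs = [
            index_of_variability(
                generate_climate_series(240, 27.0, shift, 1.0, seed=s,
                                        fut_start_year=2011),
                (2001, 2010), (2011, 2020)).iv
            for s in range(100)
        ]
        se = np.std(ivs, ddof=1) / np.sqrt(len(ivs))
        assert abs(np.mean(ivs) - shift) <= 3 * se

    def test_same_seed_reproduces_the_series(self):
        a = generate_climate_series(60, 27.0, 1.0, 0.5, seed=9, fut_start_year=2003)
        b = generate_climate_series(60, 27.0, 1.0, 0.5, seed=9, fut_start_year=2003)
        pd.testing.assert_series_equal(a.values, b.values)

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_climate_series(12, 27.0, 1.0, 0.5, seed=0)
        with pytest.raises(ValueError):
            generate_climate_series(60, 27.0, 1.0, 0.0, seed=0)


class TestTraitFixture:
    def test_spot_checked_published_cells(self, trait_fixture):
        scores = score_groups(trait_fixture)
        assert scores.loc["small_pelagic", "EA2"] == 1.000  # resilience row
        assert scores.loc["demersal", "EE1"] == 0.000
        assert round_half_up(scores.loc["coral_reef_fish", "ES1"], 3) == 0.375

    def test_every_group_cell_matches(self, trait_fixture):
        scores = score_groups(trait_fixture)
        for trait, per_group in GROUP_TRAIT_SCORES.items():
            if trait.startswith("EH"):
                continue
            for group, expected in per_group.items():
                assert round_half_up(scores.loc[group, trait], 3) == expected

    def test_fixture_is_deterministic(self):
        assert generate_trait_fixture() == generate_trait_fixture()


def test_survey_generation_needs_valid_scenarios():
    with pytest.raises(ValueError):
        CommunityScenario(name="Mafia", n=0)
    with pytest.raises(ValueError):
        CommunityScenario(name="Mafia", n=5, p_fish=1.5)
    with pytest.raises(ValueError):
        CommunityScenario(name="Mafia", n=5,
                          consumption={"demersal": 0.5, "cephalopods": 0.4})
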