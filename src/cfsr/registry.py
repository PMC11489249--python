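"""Indicator registry: codes, question types, directions and dimension membership.

The registry mirrors the assessment's indicator table: each indicator has a
code (SH2, SS3, EA1, ...), belongs to one risk dimension, sits inside a
named indicator group (the level at which dimension indices average), and
is backed by zero or more survey questions.  Resource-side indicators
(EH/EE/ES/EA) carry no questions — they are produced by the climate and
ecology stages.

The community set and the registry itself are configuration, not code, so
the framework can be ported to other regions; :func:`default_registry`
ships the Tanzania study layout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Mapping

import yaml

QUESTION_TYPES = frozenset(
    {"yes_no", "likert_1_4", "proportion", "count", "category", "composite"}
)
DIRECTIONS = frozenset({"risk_increasing", "protective"})
SOCIAL_DIMENSIONS = (
    "social_hazard",
    "social_exposure",
    "social_sensitivity",
    "social_adaptive_capacity",
)
RESOURCE_DIMENSIONS = (
    "resource_hazard",
    "resource_exposure",
    "resource_sensitivity",
    "resource_adaptive_capacity",
)
DIMENSIONS = frozenset(SOCIAL_DIMENSIONS + RESOURCE_DIMENSIONS)
ADAPTIVE_DIMENSIONS = frozenset(
    {"social_adaptive_capacity", "resource_adaptive_capacity"}
)

#: Data-quality grades by provenance class (empirically measured/modelled
#: data is most trusted; unassessed indicators are graded 0).
CONFIDENCE_BY_SOURCE = {
    "empirical": 3,
    "limited_estimate": 2,
    "expert_or_survey": 1,
    "not_assessed": 0,
}

DEFAULT_COMMUNITIES = ("Mafia", "Pemba", "Tanga", "Unguja")


@dataclass(frozen=True)
class QuestionSpec:
    """One survey question feeding an indicator."""

    qid: str
    qtype: str
    direction: str = "risk_increasing"
    #: ordinal map for ``category`` questions, category -> unit score
    category_map: Mapping[str, float] | None = None
    #: saturation cap for ``count`` questions (score = min(count, cap)/cap)
    count_cap: int = 10

    def __post_init__(self) -> None:
        if self.qtype not in QUESTION_TYPES:
            raise ValueError(f"unknown question type {self.qtype!r} for {self.qid!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r} for {self.qid!r}")
        if self.qtype == "category" and not self.category_map:
            raise ValueError(f"category question {self.qid!r} needs a category_map")


@dataclass(frozen=True)
class IndicatorSpec:
    """A named indicator: its code, dimension, group, questions and provenance."""

    code: str
    dimension: str
    indicator: str  # group name; dimension indices average over groups
    questions: tuple[QuestionSpec, ...] = ()
    source_class: str = "expert_or_survey"
    #: explicit confidence override (e.g. mixed empirical/expert inputs);
    #: when None the grade follows ``source_class``
    confidence: float | None = None
    direction: str = "risk_increasing"

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r} for {self.code!r}")
        if self.source_class not in CONFIDENCE_BY_SOURCE:
            raise ValueError(f"unknown source class {self.source_class!r}")
        if self.direction == "protective" and self.dimension not in ADAPTIVE_DIMENSIONS:
            raise ValueError(
                f"protective direction outside adaptive capacity: {self.code!r}"
            )

    @property
    def resolved_confidence(self) -> float:
        if self.confidence is not None:
            return self.confidence
        return float(CONFIDENCE_BY_SOURCE[self.source_class])


@dataclass(frozen=True)
class Registry:
    """Immutable collection of indicator specs plus the community set."""

    indicators: tuple[IndicatorSpec, ...]
    communities: tuple[str, ...] = DEFAULT_COMMUNITIES

    def __post_init__(self) -> None:
        codes = [spec.code for spec in self.indicators]
        dupes = {c for c in codes if codes.count(c) > 1}
        if dupes:
            raise ValueError(f"duplicate indicator codes: {sorted(dupes)}")
        qids = [q.qid for spec in self.indicators for q in spec.questions]
        dupes = {q for q in qids if qids.count(q) > 1}
        if dupes:
            raise ValueError(f"question ids appear under two indicators: {sorted(dupes)}")

    def __iter__(self) -> Iterator[IndicatorSpec]:
        return iter(self.indicators)

    def __getitem__(self, code: str) -> IndicatorSpec:
        for spec in self.indicators:
            if spec.code == code:
                return spec
        raise KeyError(code)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(spec.code for spec in self.indicators)

    def question(self, qid: str) -> tuple[IndicatorSpec, QuestionSpec]:
        for spec in self.indicators:
            for q in spec.questions:
                if q.qid == qid:
                    return spec, q
        raise KeyError(qid)

    @property
    def question_ids(self) -> tuple[str, ...]:
        return tuple(q.qid for spec in self.indicators for q in spec.questions)

    def dimension_codes(self, dimension: str) -> tuple[str, ...]:
        return tuple(s.code for s in self.indicators if s.dimension == dimension)

    def groups(self, dimension: str) -> dict[str, tuple[str, ...]]:
        """Indicator groups of a dimension, group name -> member codes."""
        out: dict[str, list[str]] = {}
        for spec in self.indicators:
            if spec.dimension == dimension:
                out.setdefault(spec.indicator, []).append(spec.code)
        return {name: tuple(codes) for name, codes in out.items()}

    def with_communities(self, communities: tuple[str, ...]) -> "Registry":
        return replace(self, communities=tuple(communities))


_EDUCATION_MAP = {
    "none": 0.0,
    "primary": 1 / 3,
    "secondary": 2 / 3,
    "university": 1.0,
}


def _q(qid, qtype, **kw):
    return QuestionSpec(qid, qtype, **kw)


def default_registry(communities: tuple[str, ...] = DEFAULT_COMMUNITIES) -> Registry:
    """The shipped registry for the four-community Tanzania assessment.

    Codes SH1-SH3, SE1-SE2, SS1-SS8, SA1-SA10 cover the social survey
    instrument; EH1-EH2, EE1-EE2, ES1-ES2, EA1-EA2 are the resource-side
    (ecological) indicators filled in by the climate and ecology stages.
    SH1 (ecological risk to resource) is composite and never read from
    the survey.
    """
    protective = {"direction": "protective"}
    indicators = (
        # --- social hazard ---
        IndicatorSpec("SH1", "social_hazard", "ecological_risk_to_resource",
                      source_class="limited_estimate"),
        IndicatorSpec("SH2", "social_hazard", "resource_user_hazard",
                      questions=(_q("shoreline_changed", "yes_no"),)),
        IndicatorSpec("SH3", "social_hazard", "resource_user_hazard",
                      questions=(_q("storm_last_5y", "yes_no"),)),
        # --- social exposure ---
        IndicatorSpec("SE1", "social_exposure", "exposure_slr",
                      questions=(_q("shoreline_eroded", "yes_no"),)),
        IndicatorSpec("SE2", "social_exposure", "exposure_storms",
                      questions=(_q("storm_impacted", "yes_no"),)),
        # --- social sensitivity ---
        IndicatorSpec("SS1", "social_sensitivity", "sensitivity_slr",
                      questions=(_q("livelihood_changed_erosion", "yes_no"),)),
        IndicatorSpec("SS2", "social_sensitivity", "sensitivity_storms",
                      questions=(_q("storm_damage", "likert_1_4"),
                                 _q("fishing_days_lost", "likert_1_4"))),
        IndicatorSpec("SS3", "social_sensitivity", "direct_dependence",
                      questions=(_q("days_fish_protein", "count"),
                                 _q("days_any_protein", "count"))),
        IndicatorSpec("SS4", "social_sensitivity", "direct_dependence",
                      source_class="limited_estimate"),  # nutrition, external
        IndicatorSpec("SS5", "social_sensitivity", "direct_dependence",
                      questions=(_q("feed_family_without_fishing", "likert_1_4"),)),
        IndicatorSpec("SS6", "social_sensitivity", "indirect_dependence",
                      questions=(_q("income_from_fishing", "proportion"),)),
        IndicatorSpec("SS7", "social_sensitivity", "indirect_dependence",
                      questions=(_q("fishing_importance", "likert_1_4"),)),
        IndicatorSpec("SS8", "social_sensitivity", "indirect_dependence",
                      questions=(_q("sell_house_if_fishing_fails", "likert_1_4"),)),
        # --- social adaptive capacity (protective: higher = more capacity) ---
        IndicatorSpec("SA1", "social_adaptive_capacity", "flexibility",
                      questions=(_q("adapt_vs_others", "likert_1_4", **protective),),
                      **protective),
        IndicatorSpec("SA2", "social_adaptive_capacity", "flexibility",
                      questions=(_q("changed_jobs_5y", "yes_no", **protective),
                                 _q("work_options", "likert_1_4", **protective),
                                 _q("skills_other_business", "likert_1_4", **protective)),
                      **protective),
        IndicatorSpec("SA3", "social_adaptive_capacity", "flexibility",
                      questions=(_q("markets_buy_fish", "count", **protective),
                                 _q("markets_sell_fish", "count", **protective)),
                      **protective),
        IndicatorSpec("SA4", "social_adaptive_capacity", "assets",
                      questions=(_q("owns_motor_boat", "yes_no", **protective),
                                 _q("owns_livestock", "yes_no", **protective),
                                 _q("house_quality", "likert_1_4", **protective),
                                 _q("savings_level", "likert_1_4", **protective)),
                      **protective),
        IndicatorSpec("SA5", "social_adaptive_capacity", "social_organization",
                      questions=(_q("management_system", "yes_no", **protective),
                                 _q("rules_enforced", "likert_1_4", **protective)),
                      **protective),
        IndicatorSpec("SA6", "social_adaptive_capacity", "social_organization",
                      questions=(_q("govt_links", "likert_1_4", **protective),
                                 _q("climate_institutions", "yes_no", **protective)),
                      **protective),
        IndicatorSpec("SA7", "social_adaptive_capacity", "learning",
                      questions=(_q("education_level", "category",
                                    category_map=_EDUCATION_MAP, **protective),
                                 _q("heard_climate_change", "yes_no", **protective),
                                 _q("noticed_community_changes", "yes_no", **protective),
                                 _q("environment_knowledge", "likert_1_4", **protective),
                                 _q("lek_importance", "likert_1_4", **protective)),
                      **protective),
        IndicatorSpec("SA8", "social_adaptive_capacity", "equity",
                      questions=(_q("women_leadership", "yes_no", **protective),
                                 _q("women_access_equality", "likert_1_4", **protective)),
                      **protective),
        IndicatorSpec("SA9", "social_adaptive_capacity", "social_cognition",
                      questions=(_q("occupation_safety", "likert_1_4", **protective),
                                 _q("environment_risk_view", "likert_1_4", **protective),
                                 _q("confidence_outcomes", "likert_1_4", **protective)),
                      **protective),
        IndicatorSpec("SA10", "social_adaptive_capacity", "agency",
                      questions=(_q("independence_value", "likert_1_4", **protective),
                                 _q("improvement_thinking", "likert_1_4", **protective),
                                 _q("personal_difference", "likert_1_4", **protective)),
                      **protective),
        # --- resource side (no survey questions) ---
        IndicatorSpec("EH1", "resource_hazard", "resource_hazard",
                      source_class="empirical"),
        IndicatorSpec("EH2", "resource_hazard", "resource_hazard",
                      source_class="empirical"),
        IndicatorSpec("EE1", "resource_exposure", "resource_exposure"),
        IndicatorSpec("EE2", "resource_exposure", "resource_exposure"),
        # sensitivity traits mix empirical life-history data with expert input
        IndicatorSpec("ES1", "resource_sensitivity", "resource_sensitivity",
                      source_class="limited_estimate", confidence=2.8),
        IndicatorSpec("ES2", "resource_sensitivity", "resource_sensitivity",
                      source_class="limited_estimate", confidence=2.8),
        IndicatorSpec("EA1", "resource_adaptive_capacity", "resource_adaptive_capacity",
                      source_class="empirical", **protective),
        IndicatorSpec("EA2", "resource_adaptive_capacity", "resource_adaptive_capacity",
                      source_class="empirical", **protective),
    )
    return Registry(indicators=indicators, communities=tuple(communities))


def load_registry(path) -> Registry:
    """Load a registry from a YAML document (same fields as the dataclasses)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    indicators = []
    for entry in doc["indicators"]:
        questions = tuple(
            QuestionSpec(
                qid=q["qid"],
                qtype=q["qtype"],
                direction=q.get("direction", "risk_increasing"),
                category_map=q.get("category_map"),
                count_cap=q.get("count_cap", 10),
            )
            for q in entry.get("questions", ())
        )
        indicators.append(
            IndicatorSpec(
                code=entry["code"],
                dimension=entry["dimension"],
                indicator=entry["indicator"],
                questions=questions,
                source_class=entry.get("source_class", "expert_or_survey"),
                confidence=entry.get("confidence"),
                direction=entry.get("direction", "risk_increasing"),
            )
        )
    communities = tuple(doc.get("communities", DEFAULT_COMMUNITIES))
    return Registry(indicators=tuple(indicators), communities=communities)
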