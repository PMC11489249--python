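"""Survey-derived social indicator scores per community.

Each indicator is a community-level summary of one or more survey
questions.  Answers are first encoded onto a common [0, 1] scale
(yes/no -> 1/0, Likert 1-4 -> (x-1)/3, proportions as-is, counts
saturated at a cap, categories through the registry's ordinal map);
community question scores are the mean over non-missing answers, so a
yes/no question's score is exactly the proportion answering "yes".
Indicator scores are the equal-weighted mean of their sub-question
scores; per-respondent composites (the direct-dependence ratio SS3 and
the asset wealth index SA4) are computed within each respondent first
and then averaged, preserving the coupling between a respondent's
answers.

Polarity: adaptive-capacity questions are capacity-increasing
("protective"); they are *not* flipped here — the inversion happens in
the vulnerability composition (1 - AC).  Reversed questionnaire items
are re-oriented at registry level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cfsr.aggregate import minmax_normalize
from cfsr.registry import IndicatorSpec, QuestionSpec, Registry


@dataclass(frozen=True)
class IndicatorScore:
    """One indicator's community value plus its data-confidence grade."""

    code: str
    community: str
    value: float
    confidence: float
    n_respondents: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"{self.code}: value {self.value} outside [0,1]")
        if not 0.0 <= self.confidence <= 3.0:
            raise ValueError(f"{self.code}: confidence outside [0,3]")


def encode_answer(qspec: QuestionSpec, answer) -> float:
    """Encode one validated answer onto the common [0, 1] scale."""
    if qspec.qtype == "yes_no":
        return float(answer)  # validation coerced yes/no to 1/0
    if qspec.qtype == "likert_1_4":
        return (float(answer) - 1.0) / 3.0
    if qspec.qtype == "proportion":
        return float(answer)
    if qspec.qtype == "count":
        return min(float(answer), qspec.count_cap) / qspec.count_cap
    if qspec.qtype == "category":
        try:
            return float(qspec.category_map[answer])
        except KeyError:
            raise ValueError(f"category {answer!r} not in map for {qspec.qid!r}") from None
    raise ValueError(f"question type {qspec.qtype!r} has no direct encoding")


def community_question_score(
    table: pd.DataFrame, qspec: QuestionSpec, community: str
) -> tuple[float, int]:
    """Mean encoded answer over a community's non-missing respondents."""
    sub = table.loc[table["community"] == community, qspec.qid]
    answers = [a for a in sub if not (isinstance(a, float) and np.isnan(a))]
    if not answers:
        raise ValueError(
            f"no non-missing answers for {qspec.qid!r} in community {community!r}"
        )
    scores = [encode_answer(qspec, a) for a in answers]
    return float(np.mean(scores)), len(answers)


def direct_dependence(dwf: float, tdwp: float) -> float:
    """Fraction of animal-protein days supplied by fish: DWF / TDWP."""
    if tdwp <= 0:
        raise ValueError("total protein days must be positive")
    if dwf < 0 or dwf > tdwp:
        raise ValueError("fish days must satisfy 0 <= DWF <= TDWP")
    return dwf / tdwp


def community_direct_dependence(
    table: pd.DataFrame, community: str, dwf_qid: str = "days_fish_protein",
    tdwp_qid: str = "days_any_protein",
) -> tuple[float, int]:
    """Community mean of per-respondent DWF/TDWP ratios.

    Respondents with TDWP = 0, a missing half of the pair, or DWF > TDWP
    are excluded (complete-case within the composite).
    """
    sub = table.loc[table["community"] == community, [dwf_qid, tdwp_qid]]
    ratios = []
    for dwf, tdwp in sub.itertuples(index=False):
        if np.isnan(dwf) or np.isnan(tdwp) or tdwp <= 0 or dwf > tdwp:
            continue
        ratios.append(direct_dependence(dwf, tdwp))
    if not ratios:
        raise ValueError(f"no scoreable dependence answers in {community!r}")
    return float(np.mean(ratios)), len(ratios)


def nutrition_indicator(
    group_protein_means: Mapping[str, float], proportions: Mapping[str, float]
) -> float:
    """Consumption-weighted community protein content, in g/100 g.

    ``group_protein_means`` are per-group means over >= 5 species'
    published protein contents.  The value stays on its natural physical
    scale here and is min-max normalized across communities afterwards.
    """
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"consumption proportions sum to {total}, expected 1")
    out = 0.0
    for group, p in proportions.items():
        if p == 0:
            continue
        if group not in group_protein_means:
            raise ValueError(f"no protein value for consumed group {group!r}")
        if group_protein_means[group] <= 0:
            raise ValueError(f"non-positive protein content for {group!r}")
        out += p * group_protein_means[group]
    return out


def indicator_score(sub_scores: Sequence[float]) -> float:
    """Equal-weighted mean of sub-question community scores."""
    if not sub_scores:
        raise ValueError("indicator needs at least one sub-score")
    for s in sub_scores:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"sub-score {s} outside [0,1]")
    return float(np.mean(sub_scores))


def asset_wealth_index(table: pd.DataFrame, spec: IndicatorSpec, community: str) -> tuple[float, int]:
    """Asset Wealth Index: per-respondent mean of asset sub-scores, then community mean."""
    if not spec.questions:
        raise ValueError("no asset questions configured")
    qids = [q.qid for q in spec.questions]
    sub = table.loc[table["community"] == community, qids]
    per_respondent = []
    for row in sub.itertuples(index=False):
        vals = [
            encode_answer(q, a)
            for q, a in zip(spec.questions, row)
            if not (isinstance(a, float) and np.isnan(a))
        ]
        if vals:
            per_respondent.append(float(np.mean(vals)))
    if not per_respondent:
        raise ValueError(f"no asset answers in community {community!r}")
    return float(np.mean(per_respondent)), len(per_respondent)


def score_social_indicators(
    table: pd.DataFrame,
    registry: Registry,
    nutrition_means: Mapping[str, float] | None = None,
    consumption: Mapping[str, Mapping[str, float]] | None = None,
    life_expectancy: Mapping[str, float] | None = None,
) -> list[IndicatorScore]:
    """Score every survey-backed social indicator for every community.

    SH1 (the composite ecological risk) is produced by the ecology stage
    and skipped here.  SS4 needs the nutrition table and consumption
    shares; it is min-max normalized across communities.  SA1's optional
    life-expectancy constant, when provided, is likewise normalized and
    averaged into SA1; when absent that sub-indicator contributes
    nothing and SA1's confidence reflects the survey question only.
    """
    scores: list[IndicatorScore] = []
    communities = list(registry.communities)

    # cross-community physical-scale indicators first
    ss4_by_community: dict[str, float] = {}
    if nutrition_means is not None and consumption is not None:
        raw = [nutrition_indicator(nutrition_means, consumption[c]) for c in communities]
        ss4_by_community = dict(zip(communities, minmax_normalize(raw)))
    life_norm: dict[str, float] = {}
    if life_expectancy is not None:
        raw = [float(life_expectancy[c]) for c in communities]
        life_norm = dict(zip(communities, minmax_normalize(raw)))

    for spec in registry:
        if not spec.dimension.startswith("social"):
            continue
        if spec.code == "SH1":
            continue  # composite, produced by the ecology stage
        for community in communities:
            if spec.code == "SS3":
                value, n = community_direct_dependence(table, community)
            elif spec.code == "SS4":
                if not ss4_by_community:
                    continue  # nutrition data not supplied
                value, n = ss4_by_community[community], 0
            elif spec.code == "SA4":
                value, n = asset_wealth_index(table, spec, community)
            else:
                subs, counts = [], []
                for q in spec.questions:
                    s, c = community_question_score(table, q, community)
                    subs.append(s)
                    counts.append(c)
                if spec.code == "SA1" and life_norm:
                    subs.append(life_norm[community])
                value = indicator_score(subs)
                n = min(counts) if counts else 0
            scores.append(
                IndicatorScore(
                    code=spec.code,
                    community=community,
                    value=value,
                    confidence=spec.resolved_confidence,
                    n_respondents=n,
                )
            )
    return scores
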