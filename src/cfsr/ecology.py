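"""Trait-based ecological risk scoring of functional seafood groups.

Five functional seafood groups (coral reef fish, small pelagics, large
pelagics, demersal species, cephalopods) are scored on exposure,
sensitivity and adaptive capacity from the life-history traits of their
main constituent families.  Each trait is banded low / moderate / high,
the bands map to {0, 0.5, 1}, family scores average into group scores,
two indicator scores average into each component, and community-level
components are consumption-weighted means over groups.  The nested
ecological risk to resource (ERR) then composes hazard, exposure and
vulnerability exactly like the social-side risk index and feeds the
social-hazard indicator SH1.

Banding criteria (boundaries fall in the moderate band):

=====  ==========================  ==============  =================  ==============
code   trait                       low             moderate           high
=====  ==========================  ==============  =================  ==============
EE1    depth/habitat               below 50 m      above 50 m         reef-associated
                                                                      or fully pelagic
EE2    feeding mode                higher          macro-invertebrate filter feeder
                                   predator        feeder
ES1    age at first maturity (y)   < 2             2-10               > 10
ES2    trophic level               < 2             2-4                > 4
EA1    latitudinal range (deg)     < 45            45-90              > 90
EA2    vulnerability to fisheries  > 66            33-66              < 33
=====  ==========================  ==============  =================  ==============

EA2 ("resilience to fisheries") bands the raw 0-100
vulnerability-to-fisheries score with inverted polarity — a highly
vulnerable stock (score >= 66) has low resilience — so the inversion is
encoded in the band boundaries; no numeric 100-x transform is applied
first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from cfsr.aggregate import risk_index, vulnerability

GROUPS = (
    "coral_reef_fish",
    "small_pelagic",
    "large_pelagic",
    "cephalopods",
    "demersal",
)

DEPTH_CLASSES = ("below_50m", "above_50m", "reef_or_pelagic_all_stages")
FEEDING_CLASSES = ("higher_predator", "macro_invertebrate_feeder", "filter_feeder")

LEVEL_SCORES = {"low": 0.0, "moderate": 0.5, "high": 1.0}

RESOURCE_TRAITS = ("EE1", "EE2", "ES1", "ES2", "EA1", "EA2")
COMPONENTS = {
    "RE": ("EE1", "EE2"),
    "RS": ("ES1", "ES2"),
    "RAC": ("EA1", "EA2"),
}


@dataclass(frozen=True)
class FamilyTraits:
    """Life-history traits of one fish family (or cephalopod family)."""

    family: str
    group: str
    depth_habitat: str
    feeding_class: str
    age_at_maturity: float  # years
    trophic_level: float
    latitudinal_range: float  # degrees of latitude spanned
    vulnerability_score: float  # 0-100, trait-based vulnerability to fisheries

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown functional group {self.group!r}")
        if self.depth_habitat not in DEPTH_CLASSES:
            raise ValueError(f"unknown depth/habitat class {self.depth_habitat!r}")
        if self.feeding_class not in FEEDING_CLASSES:
            raise ValueError(f"unknown feeding class {self.feeding_class!r}")
        if not self.age_at_maturity > 0:
            raise ValueError("age at maturity must be positive")
        if not 1.0 <= self.trophic_level <= 5.5:
            raise ValueError("trophic level out of the plausible [1, 5.5] range")
        if not 0 < self.latitudinal_range <= 180:
            raise ValueError("latitudinal range must be in (0, 180] degrees")
        if not 0 <= self.vulnerability_score <= 100:
            raise ValueError("vulnerability-to-fisheries score must be in [0, 100]")


def classify_trait_level(trait: str, value) -> str:
    """Band one trait value into low / moderate / high."""
    if trait == "EE1":
        if value not in DEPTH_CLASSES:
            raise ValueError(f"unknown depth/habitat class {value!r}")
        return {"below_50m": "low", "above_50m": "moderate",
                "reef_or_pelagic_all_stages": "high"}[value]
    if trait == "EE2":
        if value not in FEEDING_CLASSES:
            raise ValueError(f"unknown feeding class {value!r}")
        return {"higher_predator": "low", "macro_invertebrate_feeder": "moderate",
                "filter_feeder": "high"}[value]
    if trait == "ES1":
        if not value > 0:
            raise ValueError("age at maturity must be positive")
        return "low" if value < 2 else ("moderate" if value <= 10 else "high")
    if trait == "ES2":
        if not 1.0 <= value <= 5.5:
            raise ValueError("trophic level out of range")
        return "low" if value < 2 else ("moderate" if value <= 4 else "high")
    if trait == "EA1":
        if not 0 < value <= 180:
            raise ValueError("latitudinal range out of range")
        return "low" if value < 45 else ("moderate" if value <= 90 else "high")
    if trait == "EA2":
        if not 0 <= value <= 100:
            raise ValueError("vulnerability score out of range")
        # inverted polarity: high fisheries vulnerability = low resilience;
        # boundary scores (33, 66) fall in the moderate band
        return "low" if value > 66 else ("moderate" if value >= 33 else "high")
    raise ValueError(f"unknown resource trait {trait!r}")


def level_to_score(level: str) -> float:
    """low -> 0, moderate -> 0.5, high -> 1."""
    try:
        return LEVEL_SCORES[level]
    except KeyError:
        raise ValueError(f"unknown level {level!r}") from None


def _trait_value(fam: FamilyTraits, trait: str):
    return {
        "EE1": fam.depth_habitat,
        "EE2": fam.feeding_class,
        "ES1": fam.age_at_maturity,
        "ES2": fam.trophic_level,
        "EA1": fam.latitudinal_range,
        "EA2": fam.vulnerability_score,
    }[trait]


def group_indicator_score(families: Sequence[FamilyTraits], trait: str) -> float:
    """Unweighted mean of banded family scores for one trait."""
    if not families:
        raise ValueError("no families to score")
    scores = [level_to_score(classify_trait_level(trait, _trait_value(f, trait)))
              for f in families]
    return sum(scores) / len(scores)


def group_component(score_a: float, score_b: float) -> float:
    """A component score is the arithmetic mean of its two indicator scores."""
    for s in (score_a, score_b):
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"indicator score {s} outside [0,1]")
    return (score_a + score_b) / 2.0


def score_groups(families: Sequence[FamilyTraits]) -> pd.DataFrame:
    """Score every functional group on all six trait indicators.

    Returns a frame indexed by group with columns EE1..EA2 plus the
    component means RE, RS, RAC.
    """
    rows = {}
    for group in GROUPS:
        members = [f for f in families if f.group == group]
        if not members:
            continue
        row = {t: group_indicator_score(members, t) for t in RESOURCE_TRAITS}
        for comp, (a, b) in COMPONENTS.items():
            row[comp] = group_component(row[a], row[b])
        rows[group] = row
    if not rows:
        raise ValueError("no scoreable groups in the trait table")
    return pd.DataFrame.from_dict(rows, orient="index")


def community_resource_component(
    group_scores: Mapping[str, float], proportions: Mapping[str, float]
) -> float:
    """Consumption-weighted mean of one component over functional groups."""
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"consumption proportions sum to {total}, expected 1")
    if any(p < 0 for p in proportions.values()):
        raise ValueError("consumption proportions must be non-negative")
    out = 0.0
    for group, p in proportions.items():
        if p == 0:
            continue
        if group not in group_scores:
            raise ValueError(f"no score for consumed group {group!r}")
        out += p * group_scores[group]
    return out


def ecological_risk_to_resource(
    rh: float, re: float, rs: float, rac: float, mode: str = "table_consistent"
) -> tuple[float, float]:
    """Compose (resource vulnerability, ERR) from the four components.

    Default composition: vulnerability = mean(RS, 1-RAC) and
    ERR = mean(mean(RH, RE), vulnerability), which keeps both in [0, 1].
    ``mode="literal"`` instead returns (RS - RAC, mean(RH, RE) + (RS - RAC)),
    which carries no range guarantee.
    """
    if mode == "literal":
        v = rs - rac
        return v, (rh + re) / 2.0 + v
    v = vulnerability(rs, rac)
    return v, risk_index(rh, re, v)


def load_traits_csv(path) -> list[FamilyTraits]:
    """Read a family trait table CSV (one row per family)."""
    table = pd.read_csv(path)
    return [
        FamilyTraits(
            family=row["family"],
            group=row["group"],
            depth_habitat=row["depth_habitat"],
            feeding_class=row["feeding_class"],
            age_at_maturity=float(row["age_at_maturity"]),
            trophic_level=float(row["trophic_level"]),
            latitudinal_range=float(row["latitudinal_range"]),
            vulnerability_score=float(row["vulnerability_score"]),
        )
        for _, row in table.iterrows()
    ]


def load_consumption_csv(path) -> dict[str, dict[str, float]]:
    """Read ``community,group,proportion`` consumption shares."""
    table = pd.read_csv(path)
    out: dict[str, dict[str, float]] = {}
    for _, row in table.iterrows():
        out.setdefault(str(row["community"]), {})[str(row["group"])] = float(
            row["proportion"]
        )
    return out
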