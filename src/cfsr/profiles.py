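"""Risk-profile quadrant classification (after Thiault et al.).

Communities are placed in a two-axis plane — combined exposure-hazard
(mean of the hazard and exposure indices) against vulnerability — and
classified into four intervention-oriented profiles:

* high exposure-hazard, high vulnerability: **greatest concern** —
  reduce resource dependency *and* build adaptive capacity;
* high exposure-hazard, low vulnerability: **potential adapters** —
  reduce dependency on the resource;
* low exposure-hazard, high vulnerability: **capacity-building
  priority** — invest in adaptive capacity;
* low/low: **lowest concern**.

Threshold values are not prescribed by the framework; the default is the
scale midpoint 0.5 on both axes, values exactly at a threshold classify
as "high", and the thresholds used are always reported alongside the
labels.
"""

from __future__ import annotations

from dataclasses import dataclass

PROFILE_LABELS = (
    "lowest_concern",
    "potential_adapters",
    "capacity_building_priority",
    "greatest_concern",
)

#: partial order of concern used by monotonicity checks: the two mixed
#: quadrants are incomparable with each other but sit between the corners
CONCERN_RANK = {
    "lowest_concern": 0,
    "potential_adapters": 1,
    "capacity_building_priority": 1,
    "greatest_concern": 2,
}


@dataclass(frozen=True)
class ProfileRule:
    exposure_hazard_threshold: float = 0.5
    vulnerability_threshold: float = 0.5

    def __post_init__(self) -> None:
        for t in (self.exposure_hazard_threshold, self.vulnerability_threshold):
            if not 0.0 < t < 1.0:
                raise ValueError(f"profile threshold {t} must lie strictly in (0,1)")


def classify_profile(
    exposure_hazard: float, vulnerability: float, rule: ProfileRule = ProfileRule()
) -> str:
    """Assign the quadrant label for one community.

    ``exposure_hazard`` is the mean of the hazard and exposure indices,
    consistent with the risk-index composition.
    """
    for name, v in (("exposure_hazard", exposure_hazard), ("vulnerability", vulnerability)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} = {v} outside [0,1]")
    high_eh = exposure_hazard >= rule.exposure_hazard_threshold
    high_v = vulnerability >= rule.vulnerability_threshold
    if high_eh and high_v:
        return "greatest_concern"
    if high_eh:
        return "potential_adapters"
    if high_v:
        return "capacity_building_priority"
    return "lowest_concern"
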