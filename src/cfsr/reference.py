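"""Published reference scores from the four-community Tanzania assessment.

These are the printed component scores of the original case study —
group-level trait scores for the five functional seafood groups, and
per-community dimension/component indices with their confidence grades.
They serve two purposes: as regression targets for the scoring code
(the trait fixture must reproduce every group cell) and as *inputs* to
the composition stage when checking that the vulnerability and risk
rules reproduce the published composite indices.
"""

from __future__ import annotations

GROUP_ORDER = (
    "coral_reef_fish",
    "small_pelagic",
    "large_pelagic",
    "cephalopods",
    "demersal",
)

#: group-level indicator scores, trait code -> per-group score
GROUP_TRAIT_SCORES: dict[str, dict[str, float]] = {
    "EH1": dict(zip(GROUP_ORDER, (0.350, 0.350, 0.350, 0.350, 0.350))),  # SST hazard
    "EH2": dict(zip(GROUP_ORDER, (0.550, 0.550, 0.550, 0.550, 0.550))),  # PP hazard
    "EE1": dict(zip(GROUP_ORDER, (1.000, 1.000, 1.000, 0.500, 0.000))),
    "EE2": dict(zip(GROUP_ORDER, (0.500, 1.000, 0.333, 0.750, 0.000))),
    "ES1": dict(zip(GROUP_ORDER, (0.375, 0.000, 0.167, 0.000, 0.500))),
    "ES2": dict(zip(GROUP_ORDER, (0.500, 0.500, 1.000, 0.750, 0.500))),
    # EA1 = latitudinal range, EA2 = resilience to fisheries
    "EA1": dict(zip(GROUP_ORDER, (0.500, 0.500, 0.833, 1.000, 0.500))),
    "EA2": dict(zip(GROUP_ORDER, (0.625, 1.000, 0.333, 0.250, 0.000))),
}

#: published component averages (mean of the two rounded indicator rows)
GROUP_COMPONENT_AVERAGES: dict[str, dict[str, float]] = {
    "RH": dict(zip(GROUP_ORDER, (0.450, 0.450, 0.450, 0.450, 0.450))),
    "RE": dict(zip(GROUP_ORDER, (0.750, 1.000, 0.667, 0.625, 0.000))),
    "RS": dict(zip(GROUP_ORDER, (0.438, 0.250, 0.584, 0.375, 0.500))),
    "RAC": dict(zip(GROUP_ORDER, (0.563, 0.750, 0.583, 0.625, 0.250))),
}

COMMUNITIES = ("Mafia", "Pemba", "Tanga", "Unguja")

#: per-community resource components (consumption-weighted) and the
#: published composites built from them
RESOURCE_COMPONENTS: dict[str, dict[str, float]] = {
    "RH": dict(zip(COMMUNITIES, (0.450, 0.450, 0.450, 0.450))),
    "RE": dict(zip(COMMUNITIES, (0.713, 0.675, 0.696, 0.626))),
    "RS": dict(zip(COMMUNITIES, (0.415, 0.448, 0.441, 0.466))),
    "RAC": dict(zip(COMMUNITIES, (0.635, 0.604, 0.640, 0.649))),
}
RESOURCE_VULNERABILITY = dict(zip(COMMUNITIES, (0.390, 0.422, 0.400, 0.408)))
ECOLOGICAL_RISK = dict(zip(COMMUNITIES, (0.486, 0.492, 0.487, 0.473)))

#: per-community social dimension indices and published composites
SOCIAL_DIMENSIONS: dict[str, dict[str, float]] = {
    "SH": dict(zip(COMMUNITIES, (0.517, 0.664, 0.521, 0.724))),
    "SE": dict(zip(COMMUNITIES, (0.550, 0.590, 0.480, 0.720))),
    "SS": dict(zip(COMMUNITIES, (0.580, 0.588, 0.519, 0.648))),
    "SAC": dict(zip(COMMUNITIES, (0.566, 0.517, 0.565, 0.585))),
}
SOCIAL_VULNERABILITY = dict(zip(COMMUNITIES, (0.507, 0.535, 0.477, 0.532)))
#: published final index; only Mafia's value is reproducible from the
#: printed dimension indices (the others were evidently composed from
#: unrounded intermediates)
CFSR_INDEX = dict(zip(COMMUNITIES, (0.520, 0.574, 0.484, 0.602)))

#: component confidence grades (resource side)
RESOURCE_CONFIDENCE = {"RH": 3.000, "RE": 1.000, "RS": 2.800, "RAC": 3.000}
RESOURCE_VULNERABILITY_CONFIDENCE = 2.900
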