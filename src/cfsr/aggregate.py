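"""Normalization, vulnerability/risk composition and confidence propagation.

The framework composes each risk index from hazard (H), exposure (E),
sensitivity (S) and adaptive capacity (AC), all on [0, 1]:

    vulnerability V = mean(S, 1 - AC)
    risk          R = mean(mean(H, E), V)

Algebraically R is the unweighted mean of (H, E, S, 1 - AC), so it is
bounded in [0, 1], symmetric in H and E, increasing in H, E and S and
decreasing in AC.  The same composition is used for the nested
ecological risk to resource and for the final community food-security
risk.  A "literal" mode exposing the alternative additive composition
mean(H, E) + (S - AC) is retained for comparison; it carries no range
guarantee.

Every indicator additionally carries a data-confidence grade 0-3
(3 = empirically measured or modelled, 2 = estimated with limited data,
1 = survey or expert elicitation, 0 = not assessed), propagated upward
as a plain mean.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np

from cfsr.registry import CONFIDENCE_BY_SOURCE


class DegenerateRangeWarning(UserWarning):
    """All values equal: min-max normalization has no spread to use."""


def _check_unit(name: str, *values: float) -> None:
    for v in values:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} expects values in [0,1], got {v}")


def minmax_normalize(values: Sequence[float]) -> list[float]:
    """Rescale values to [0, 1] by (x - min) / (max - min).

    With a degenerate range (max = min) every value maps to 0.5 and a
    :class:`DegenerateRangeWarning` is emitted; there is no spread to
    rank the communities on.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("min-max normalization needs at least 2 values")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        warnings.warn(
            "all values equal; mapping everything to 0.5", DegenerateRangeWarning
        )
        return [0.5] * arr.size
    return list((arr - lo) / (hi - lo))


def vulnerability(sensitivity: float, adaptive_capacity: float, mode: str = "table_consistent") -> float:
    """Compose sensitivity and adaptive capacity into vulnerability.

    Default: mean(S, 1 - AC).  ``mode="literal"`` returns S - AC (may be
    negative).
    """
    if mode == "literal":
        return sensitivity - adaptive_capacity
    _check_unit("vulnerability", sensitivity, adaptive_capacity)
    return (sensitivity + (1.0 - adaptive_capacity)) / 2.0


def risk_index(hazard: float, exposure: float, vuln: float) -> float:
    """Risk = mean(mean(H, E), V); equals mean(H, E, S, 1-AC) algebraically."""
    _check_unit("risk_index", hazard, exposure, vuln)
    return ((hazard + exposure) / 2.0 + vuln) / 2.0


def assign_confidence(source_class: str) -> int:
    """Map a data-provenance class to its 0-3 confidence grade."""
    try:
        return CONFIDENCE_BY_SOURCE[source_class]
    except KeyError:
        raise ValueError(
            f"unknown data-source class {source_class!r}; "
            f"expected one of {sorted(CONFIDENCE_BY_SOURCE)}"
        ) from None


def propagate_confidence(child_confidences: Iterable[float]) -> float:
    """Aggregate child confidences upward as an unweighted mean."""
    vals = list(child_confidences)
    if not vals:
        raise ValueError("no child confidences to propagate")
    for v in vals:
        if not 0.0 <= v <= 3.0:
            raise ValueError(f"confidence {v} outside [0,3]")
    return float(np.mean(vals))
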