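"""Half-up decimal rounding, matching how the published tables were formatted."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round with ties away from zero (0.4375 -> 0.438), not banker's rounding.

    Published score tables round half-up, so reproducing printed cells
    requires this instead of the built-in ``round``.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
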