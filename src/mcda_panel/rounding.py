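"""Round-half-up display rounding.

All internal computation is done at full float precision; rounding is applied
only when numbers are rendered (means/SDs to 1 dp, value estimates to 2 dp,
percentages to 1 dp). Python's built-in ``round`` is banker's rounding, which
disagrees with the half-up convention used in the study tables (e.g. a mean
of 4.55 must display as 4.6, not 4.5), so rendering goes through here.
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    The float is first quantized through its shortest repr so that values
    like 0.43651 (stored as 0.43650999...) round the way they print.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
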