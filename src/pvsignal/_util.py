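"""Shared helpers: label normalization and display rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def norm_label(label: str) -> str:
    """Normalize a drug or PT label: collapse whitespace, lowercase.

    All label matching in the package (drug catalog lookups, SMQ term
    matching) goes through this, so "Anaphylactic  Reaction" and
    "anaphylactic reaction" are the same term.
    """
    return " ".join(str(label).split()).lower()


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as safety tables are printed.

    Python's built-in round() is banker's rounding; published
    pharmacovigilance tables round 0.05 up to 0.1, so display values and
    any comparison against printed numbers must use this instead.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage of ``count`` over ``denominator`` rounded half-up.

    Returns 0.0 for an empty denominator so header-only tables stay
    well-defined.
    """
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * count / denominator, ndigits)
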