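"""Small shared helpers: reporting-grade rounding and DNA alphabet checks."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_RESIDUES = frozenset("ACGTN")


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties going away from zero, as printed tables do.

    Python's built-in round() uses banker's rounding, which turns an exact
    0.125 into 0.12; published codon-usage tables print 0.13.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_residues(seq: str) -> str:
    """Uppercase and map U->T; validation is left to callers."""
    return seq.upper().replace("U", "T")
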