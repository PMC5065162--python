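"""Small shared helpers: rounding, sequence utilities."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
DNA_ALPHABET = frozenset("ACGTN")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), like printed percentages.

    Python's builtin round() is banker's rounding; percentages quoted in the
    literature (e.g. "8.6%") use half-up, so summaries do too.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, label: str = "sequence") -> str:
    """Uppercase and check a DNA string against the {A,C,G,T,N} alphabet.

    Raises ValueError naming the first offending position (1-based).
    """
    if not seq:
        raise ValueError(f"{label} is empty")
    up = seq.upper()
    for i, c in enumerate(up):
        if c not in DNA_ALPHABET:
            raise ValueError(
                f"{label} has non-IUPAC character {c!r} at position {i + 1}"
            )
    return up
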