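"""Shared helpers: DNA alphabet checks, reverse complement, half-up rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
IUPAC_EXTRA = set("RYSWKMBDHV")


def reverse_complement(seq: str) -> str:
    return seq.translate(DNA_COMPLEMENT)[::-1]


def is_strict_dna(seq: str) -> bool:
    """True if seq contains only A/C/G/T (no N, no ambiguity codes)."""
    return not set(seq) - set("ACGT")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero, which for the non-negative quantities
    reported here is the familiar 'half-up' convention.

    Python's built-in round() uses banker's rounding (2.5 -> 2), which does
    not reproduce conventional table percentages (2.5 -> 3).  Decimal is used
    so that values sitting exactly on a half boundary are not perturbed by
    binary floating-point representation.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def percent_int(count: int, total: int) -> int:
    """Integer percentage, half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(round_half_up(100.0 * count / total))
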