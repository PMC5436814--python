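"""IUPAC nucleotide codes: expansion, degenerate matching and complementation.

Degenerate primers are written with IUPAC ambiguity codes (R = A/G,
W = A/T, ...).  A primer position *matches* a template base when the base is
in the code's expansion.  An ``N`` in the *template* matches nothing: an
uncalled base gives no evidence of primer annealing, so matching is
conservative.
"""

from __future__ import annotations

IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Codes valid in a primer (all 15) and in a stored reference sequence.
PRIMER_ALPHABET = frozenset(IUPAC_EXPANSION)
SEQUENCE_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Reverse complement, degenerate-code aware (R<->Y, K<->M, ...)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(primer_base: str, target_base: str) -> bool:
    """True iff ``target_base`` is in the expansion of ``primer_base``.

    ``N`` in the target matches nothing, regardless of the primer code.
    Raises ``ValueError`` for an invalid primer code or target base.
    """
    try:
        expansion = IUPAC_EXPANSION[primer_base]
    except KeyError:
        raise ValueError(f"invalid IUPAC code in primer: {primer_base!r}") from None
    if target_base == "N":
        return False
    if target_base not in "ACGT":
        raise ValueError(f"invalid target base: {target_base!r}")
    return target_base in expansion


def codes_intersect(code_a: str, code_b: str) -> bool:
    """True iff two IUPAC codes share at least one concrete base."""
    try:
        ea = IUPAC_EXPANSION[code_a]
        eb = IUPAC_EXPANSION[code_b]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code: {exc.args[0]!r}") from None
    return bool(ea & eb)


def count_mismatches(primer: str, window: str) -> int:
    """Number of primer positions whose code does not cover the aligned base.

    ``window`` must have the same length as ``primer``.  Template ``N``
    counts as a mismatch at every position.
    """
    if len(primer) != len(window):
        raise ValueError("primer and window lengths differ")
    n = 0
    for p, t in zip(primer, window):
        if t == "N" or t not in IUPAC_EXPANSION[p]:
            n += 1
    return n


def matches_with_at_most(primer: str, seq: str, pos: int, max_mismatch: int) -> int | None:
    """Mismatch count of ``primer`` placed at ``pos`` on ``seq``, or None.

    Returns ``None`` when the placement runs off the sequence or exceeds
    ``max_mismatch`` (early exit).
    """
    end = pos + len(primer)
    if pos < 0 or end > len(seq):
        return None
    n = 0
    window = seq[pos:end]
    for p, t in zip(primer, window):
        if t == "N" or t not in IUPAC_EXPANSION[p]:
            n += 1
            if n > max_mismatch:
                return None
    return n


def longest_concrete_run(primer: str) -> tuple[str, int]:
    """Longest substring of a primer containing only A/C/G/T.

    Used as an exact-match seed when locating degenerate primers in reads.
    Returns ``(substring, offset_within_primer)``.
    """
    best = ("", 0)
    start = None
    for i, c in enumerate(primer + "$"):
        if c in "ACGT":
            if start is None:
                start = i
        else:
            if start is not None and i - start > len(best[0]):
                best = (primer[start:i], start)
            start = None
    return best
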