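"""Read processing: pair merging, construct trimming, retention filters.

Every stage returns a :class:`StageAccounting` whose counts are conserved
(``n_in == n_out + sum(rejections)``), mirroring the per-sample read
ledgers kept when validating a sequencing run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assays import AssayDefinition
from .iupac import longest_concrete_run, matches_with_at_most, reverse_complement


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str
    quality: str


@dataclass
class StageAccounting:
    stage: str
    n_in: int = 0
    n_out: int = 0
    n_rejected_by_reason: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.n_rejected_by_reason[reason] = self.n_rejected_by_reason.get(reason, 0) + 1

    @property
    def conserved(self) -> bool:
        return self.n_in == self.n_out + sum(self.n_rejected_by_reason.values())

    def as_row(self) -> dict:
        row = {"stage": self.stage, "n_in": self.n_in, "n_out": self.n_out}
        for reason, n in sorted(self.n_rejected_by_reason.items()):
            row[f"rejected_{reason}"] = n
        return row


def _to_u8(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _qual_to_arr(q: str) -> np.ndarray:
    return _to_u8(q).astype(np.int16) - 33


_SEED_LEN = 16


def _candidate_offsets(s1: str, s2: str, min_overlap: int) -> set[int]:
    """Offsets of s2 within s1's coordinates, found by exact k-mer seeding.

    An offset ``o`` means s2[0] aligns with s1[o].  Seeds are taken from
    several positions of s2 so that a sequencing error in one seed does not
    lose the true offset; a brute-force scan is the caller's fallback.
    """
    offsets: set[int] = set()
    max_off = len(s1) - min_overlap
    for seed_pos in (0, _SEED_LEN, 2 * _SEED_LEN, 3 * _SEED_LEN):
        if seed_pos + _SEED_LEN > len(s2):
            break
        seed = s2[seed_pos : seed_pos + _SEED_LEN]
        start = 0
        while True:
            idx = s1.find(seed, start)
            if idx < 0:
                break
            off = idx - seed_pos
            if 0 <= off <= max_off:
                offsets.add(off)
            start = idx + 1
    return offsets


def _overlap_stats(a1, a2, off: int) -> tuple[int, int]:
    """(overlap_length, n_mismatch) for s2 placed at offset ``off`` in s1."""
    n = min(len(a1) - off, len(a2))
    if n <= 0:
        return 0, 0
    seg1 = a1[off : off + n]
    seg2 = a2[:n]
    return n, int(np.count_nonzero(seg1 != seg2))


def merge_pairs(
    pairs,
    min_overlap: int = 20,
    max_mismatch_rate: float = 0.1,
) -> tuple[list[Read], StageAccounting]:
    """Merge read pairs by their best 3' overlap.

    Read 2 is reverse-complemented and slid along read 1; the offset with
    the lowest mismatch rate over an overlap of at least ``min_overlap``
    wins (ties: longer overlap).  Disagreeing positions take the
    higher-quality base and keep the *lower* of the two qualities;
    agreeing positions keep the higher quality, capped at Q41.  Unmerged
    pairs are rejected with a reason, never dropped silently.
    """
    merged: list[Read] = []
    acct = StageAccounting("merge", n_in=len(pairs))
    for pair in pairs:
        s1 = pair.r1_sequence
        s2 = reverse_complement(pair.r2_sequence)
        q1 = pair.r1_quality
        q2 = pair.r2_quality[::-1]
        candidates = _candidate_offsets(s1, s2, min_overlap)
        a1, a2 = _to_u8(s1), _to_u8(s2)
        if not candidates:  # seeding failed: exhaustive offset scan
            candidates = set(range(0, max(0, len(s1) - min_overlap) + 1))
        best = None  # (mismatch_rate, -overlap, offset, n_mm)
        for off in candidates:
            n, mm = _overlap_stats(a1, a2, off)
            if n < min_overlap:
                continue
            key = (mm / n, -n, off)
            if best is None or key < best[:3]:
                best = (mm / n, -n, off, mm)
        if best is None:
            acct.reject("no_overlap")
            continue
        rate, neg_n, off, _ = best
        if rate > max_mismatch_rate:
            acct.reject("mismatch_rate")
            continue
        n = -neg_n
        qa1, qa2 = _qual_to_arr(q1), _qual_to_arr(q2)
        seg1, seg2 = a1[off : off + n], a2[:n]
        qs1, qs2 = qa1[off : off + n], qa2[:n]
        agree = seg1 == seg2
        take1 = qs1 >= qs2
        cons = np.where(take1, seg1, seg2)
        consq = np.where(
            agree, np.minimum(np.maximum(qs1, qs2), 41), np.minimum(qs1, qs2)
        )
        out_seq = s1[:off] + cons.tobytes().decode("ascii") + s2[n:]
        out_qual = (
            q1[:off]
            + (consq.astype(np.uint8) + 33).tobytes().decode("ascii")
            + q2[n:]
        )
        merged.append(Read(pair.read_id, out_seq, out_qual))
    acct.n_out = len(merged)
    return merged, acct


class _PrimerLocator:
    """Locates a degenerate primer near a read end.

    Fast path: exact search for the primer's longest concrete (A/C/G/T-only)
    run, then full degenerate verification at the implied position.  Slow
    path: positional scan with mismatch counting.
    """

    def __init__(self, primer: str, max_mismatch: int):
        self.primer = primer
        self.max_mismatch = max_mismatch
        self.seed, self.seed_off = longest_concrete_run(primer)

    def find(self, seq: str, lo: int, hi: int) -> tuple[int, int] | None:
        """Best (position, n_mismatch) with position in [lo, hi]."""
        lo = max(lo, 0)
        hi = min(hi, len(seq) - len(self.primer))
        if hi < lo:
            return None
        if self.seed:
            start = lo + self.seed_off
            while True:
                idx = seq.find(self.seed, start, hi + self.seed_off + len(self.seed))
                if idx < 0:
                    break
                pos = idx - self.seed_off
                if lo <= pos <= hi:
                    mm = matches_with_at_most(self.primer, seq, pos, self.max_mismatch)
                    if mm is not None:
                        return pos, mm
                start = idx + 1
        best = None
        for pos in range(lo, hi + 1):
            mm = matches_with_at_most(self.primer, seq, pos, self.max_mismatch)
            if mm is not None and (best is None or mm < best[1]):
                best = (pos, mm)
                if mm == 0:
                    break
        return best


def trim_construct(
    reads,
    assay: AssayDefinition,
    max_primer_mismatch: int = 1,
    search_window: int = 25,
) -> tuple[list[Read], StageAccounting]:
    """Trim spacers and assay primers off merged reads, keeping the insert.

    The forward primer must start within the first ``search_window``
    positions (the longest spacer is 17 nt) and the reverse-complemented
    reverse primer must end within the last ``search_window`` positions;
    matches deeper in the read do not trigger trimming, preventing
    mid-read false trims.  Reads lacking either primer are rejected.
    """
    fwd = _PrimerLocator(assay.forward_primer, max_primer_mismatch)
    rev_rc = reverse_complement(assay.reverse_primer)
    rev = _PrimerLocator(rev_rc, max_primer_mismatch)
    out: list[Read] = []
    acct = StageAccounting("trim", n_in=len(reads))
    for read in reads:
        seq = read.sequence
        hit_f = fwd.find(seq, 0, search_window)
        if hit_f is None:
            acct.reject("no_forward_primer")
            continue
        insert_start = hit_f[0] + len(assay.forward_primer)
        lo = len(seq) - len(rev_rc) - search_window
        hit_r = rev.find(seq, max(lo, insert_start), len(seq) - len(rev_rc))
        if hit_r is None:
            acct.reject("no_reverse_primer")
            continue
        insert_end = hit_r[0]
        out.append(
            Read(read.read_id, seq[insert_start:insert_end], read.quality[insert_start:insert_end])
        )
    acct.n_out = len(out)
    return out, acct


def retention_filters(
    reads,
    min_length: int = 100,
    drop_singletons: bool = True,
) -> tuple[list[Read], StageAccounting]:
    """Retention filters: drop short inserts, then sample-level singletons.

    A singleton is a sequence whose exact string occurs once in the sample
    (multiplicity counted after the length filter).  The 100 bp boundary is
    inclusive: a 100 bp insert is retained.
    """
    acct = StageAccounting("retention", n_in=len(reads))
    long_enough = []
    for read in reads:
        if len(read.sequence) < min_length:
            acct.reject("short")
        else:
            long_enough.append(read)
    if drop_singletons:
        counts: dict[str, int] = {}
        for read in long_enough:
            counts[read.sequence] = counts.get(read.sequence, 0) + 1
        out = []
        for read in long_enough:
            if counts[read.sequence] == 1:
                acct.reject("singleton")
            else:
                out.append(read)
    else:
        out = long_enough
    acct.n_out = len(out)
    return out, acct
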