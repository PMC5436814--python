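"""Metabarcoding assay definitions and in-silico PCR.

An assay is a degenerate forward/reverse primer pair, optionally a 3'-blocked
blocking primer that suppresses a non-target group, and the four spacer
constructs used in two-step library preparation (the spacer shifts the
assay primer relative to the sequencing primer to add nucleotide diversity
on the flowcell).

In-silico PCR scans a reference sequence on both strands for a forward
primer site and a downstream reverse-complemented reverse primer site and
extracts the intervening amplicon.  Amplicon length is reported
primer-inclusive (forward primer start to reverse primer end), the
convention in which amplicon sizes are normally quoted; the insert
(primer-free) sequence is kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .iupac import (
    PRIMER_ALPHABET,
    matches_with_at_most,
    codes_intersect,
    reverse_complement,
)

# Illumina Nextera-style sequencing-primer regions of the two-step construct.
SEQPRIMER_FWD = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"
SEQPRIMER_REV = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"


@dataclass(frozen=True)
class SpacerSet:
    """One of the four spacer combinations (sets E-H) of the library construct."""

    name: str
    forward_spacer: str
    reverse_spacer: str
    forward_seqprimer: str = SEQPRIMER_FWD
    reverse_seqprimer: str = SEQPRIMER_REV


#: Spacer sets E-H; identical across assays, 7-17 nt per direction.
SPACER_SETS: dict[str, SpacerSet] = {
    "E": SpacerSet("E", "TCCTATG", "CGTACTAGATGTACGA"),
    "F": SpacerSet("F", "ATGCTACAGT", "TCACTAGCTGACGC"),
    "G": SpacerSet("G", "CGAGGCTACAACTC", "GAGTAGCTGA"),
    "H": SpacerSet("H", "GATACGATCTCGCACTC", "ATCGGCT"),
}


@dataclass(frozen=True)
class AssayDefinition:
    name: str
    forward_primer: str
    reverse_primer: str
    blocking_primer: str | None = None
    blocking_3p_blocked: bool = False
    spacer_sets: dict[str, SpacerSet] = field(default_factory=lambda: dict(SPACER_SETS))
    expected_length_range: tuple[int, int] = (100, 500)

    def __post_init__(self) -> None:
        for label, primer in (
            ("forward", self.forward_primer),
            ("reverse", self.reverse_primer),
        ):
            if not primer:
                raise ValueError(f"{label} primer is empty")
            bad = set(primer) - PRIMER_ALPHABET
            if bad:
                raise ValueError(f"{label} primer has non-IUPAC characters: {bad}")
        if self.blocking_primer is not None:
            bad = set(self.blocking_primer) - PRIMER_ALPHABET
            if bad:
                raise ValueError(f"blocking primer has non-IUPAC characters: {bad}")
        lo, hi = self.expected_length_range
        if lo > hi:
            raise ValueError("expected_length_range min exceeds max")


def mol16s_assay() -> AssayDefinition:
    """Mollusc 16S mini-barcode assay (degenerate; fish-blocking primer)."""
    return AssayDefinition(
        name="MOL16S",
        forward_primer="RRWRGACRAGAAGACCCT",
        reverse_primer="ARTCCAACATCGAGGT",
        blocking_primer="AGGTCGTAACCCCCTRG",
        blocking_3p_blocked=True,  # C3 spacer on the 3' end prevents extension
        expected_length_range=(100, 500),
    )


def sph16s_assay() -> AssayDefinition:
    """Sphaeriid-clam-specific 16S assay (non-degenerate, ~299 bp amplicon)."""
    return AssayDefinition(
        name="SPH16S",
        forward_primer="TAGGGGAAGGTATGAATGGTTTG",
        reverse_primer="ACATCGAGGTCGCAACC",
        expected_length_range=(100, 500),
    )


BUILTIN_ASSAYS = {"MOL16S": mol16s_assay, "SPH16S": sph16s_assay}


@dataclass(frozen=True)
class InSilicoAmplicon:
    """One predicted amplicon on a reference sequence.

    ``start``/``end`` are 0-based half-open plus-strand coordinates of the
    primer-inclusive amplicon.  ``sequence`` and ``insert`` are given in
    amplicon orientation (forward primer first).
    """

    accession: str
    start: int
    end: int
    n_mismatch_fwd: int
    n_mismatch_rev: int
    orientation: str  # "plus" | "minus"
    sequence: str
    insert: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _scan_primer_sites(primer: str, seq: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (position, n_mismatch) placements of a degenerate primer."""
    hits = []
    for pos in range(len(seq) - len(primer) + 1):
        mm = matches_with_at_most(primer, seq, pos, max_mismatch)
        if mm is not None:
            hits.append((pos, mm))
    return hits


def _find_on_strand(
    assay: AssayDefinition, seq: str, max_mismatch: int, length_range: tuple[int, int]
) -> list[tuple[int, int, int, int]]:
    """(start, end, mm_fwd, mm_rev) of amplicons on the given strand."""
    fwd = assay.forward_primer
    rev_rc = reverse_complement(assay.reverse_primer)
    fwd_hits = _scan_primer_sites(fwd, seq, max_mismatch)
    rev_hits = _scan_primer_sites(rev_rc, seq, max_mismatch)
    lo, hi = length_range
    out = []
    for fpos, fmm in fwd_hits:
        for rpos, rmm in rev_hits:
            end = rpos + len(rev_rc)
            if rpos < fpos + len(fwd):
                continue  # reverse site must lie downstream of the forward site
            length = end - fpos
            if lo <= length <= hi:
                out.append((fpos, end, fmm, rmm))
    return out


def find_amplicons(
    assay: AssayDefinition,
    record,
    max_mismatch: int = 0,
    length_range: tuple[int, int] | None = None,
) -> list[InSilicoAmplicon]:
    """Predict amplicons of an assay on one reference record.

    Both strands are scanned; minus-strand hits are reported in plus-strand
    coordinates with ``orientation="minus"`` and their sequence given in
    amplicon orientation.  Results are sorted by start coordinate.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    seq = record.sequence if hasattr(record, "sequence") else str(record)
    accession = getattr(record, "accession", "?")
    window = length_range or assay.expected_length_range
    flen, rlen = len(assay.forward_primer), len(assay.reverse_primer)
    amplicons = []
    for start, end, fmm, rmm in _find_on_strand(assay, seq, max_mismatch, window):
        sub = seq[start:end]
        amplicons.append(
            InSilicoAmplicon(
                accession, start, end, fmm, rmm, "plus", sub, sub[flen : len(sub) - rlen]
            )
        )
    rc = reverse_complement(seq)
    n = len(seq)
    for start, end, fmm, rmm in _find_on_strand(assay, rc, max_mismatch, window):
        sub = rc[start:end]
        amplicons.append(
            InSilicoAmplicon(
                accession,
                n - end,
                n - start,
                fmm,
                rmm,
                "minus",
                sub,
                sub[flen : len(sub) - rlen],
            )
        )
    amplicons.sort(key=lambda a: (a.start, a.end, a.orientation))
    return amplicons


@dataclass(frozen=True)
class SpecificityReport:
    """Per-record amplification predictions plus a per-species summary."""

    records: pd.DataFrame  # accession, species, amplifies, length, mismatches
    species: pd.DataFrame  # species, amplifies, n_records, n_amplifying


def specificity_matrix(
    assay: AssayDefinition, database, max_mismatch: int = 0
) -> SpecificityReport:
    """Evaluate which reference records/species an assay amplifies in silico."""
    rows = []
    for rec in database:
        hits = find_amplicons(assay, rec, max_mismatch=max_mismatch)
        if hits:
            best = min(hits, key=lambda a: a.n_mismatch_fwd + a.n_mismatch_rev)
            rows.append(
                dict(
                    accession=rec.accession,
                    species=rec.species,
                    amplifies=True,
                    length=best.length,
                    mismatches=best.n_mismatch_fwd + best.n_mismatch_rev,
                )
            )
        else:
            rows.append(
                dict(
                    accession=rec.accession,
                    species=rec.species,
                    amplifies=False,
                    length=pd.NA,
                    mismatches=pd.NA,
                )
            )
    records = pd.DataFrame(
        rows, columns=["accession", "species", "amplifies", "length", "mismatches"]
    )
    if records.empty:
        species = pd.DataFrame(
            columns=["species", "amplifies", "n_records", "n_amplifying"]
        )
    else:
        grouped = records.groupby("species", sort=False)["amplifies"]
        species = pd.DataFrame(
            {
                "species": grouped.any().index,
                "amplifies": grouped.any().to_numpy(),
                "n_records": grouped.size().to_numpy(),
                "n_amplifying": grouped.sum().to_numpy(),
            }
        )
    return SpecificityReport(records=records, species=species)


@dataclass(frozen=True)
class BlockingOverlap:
    applicable: bool
    overlap_length: int = 0
    extension_blocked: bool = False


def blocking_overlap_report(assay: AssayDefinition) -> BlockingOverlap:
    """Overlap between the reverse primer's 3' end and the blocking primer's 5' end.

    Both oligos anneal to the same strand in the same orientation, the
    blocking primer shifted so that its 5' end overlaps the reverse primer's
    3' end and extends into taxon-specific sequence.  The overlap is the
    longest k for which the last k reverse-primer codes are compatible
    (IUPAC expansions intersect) with the first k blocking-primer codes.
    """
    if assay.blocking_primer is None:
        return BlockingOverlap(applicable=False)
    rev, block = assay.reverse_primer, assay.blocking_primer
    best = 0
    for k in range(1, min(len(rev), len(block)) + 1):
        if all(codes_intersect(a, b) for a, b in zip(rev[-k:], block[:k])):
            best = k
    return BlockingOverlap(
        applicable=True, overlap_length=best, extension_blocked=assay.blocking_3p_blocked
    )
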