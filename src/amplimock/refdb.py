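"""Curated reference amplicon database with taxonomy, and amplicon-level
OTU collapsing.

References are short mitochondrial 16S sequences, one per GenBank-style
accession, tied to a species and a higher taxon through a delimited
taxonomy table.  Several references can share an identical amplicon for a
given assay; collapsing them into amplicon OTUs makes explicit which
species an exact-matching read can and cannot discriminate.

For testing and simulation the module can fabricate a fully synthetic
database whose templates carry real primer annealing sites around random
species-specific inserts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assays import AssayDefinition, find_amplicons, mol16s_assay, sph16s_assay
from .iupac import IUPAC_EXPANSION, SEQUENCE_ALPHABET, reverse_complement


@dataclass(frozen=True)
class ReferenceRecord:
    accession: str
    species: str
    higher_taxon: str
    sequence: str
    source: str = "fixture"  # downloaded | generated | fixture

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - SEQUENCE_ALPHABET - set(IUPAC_EXPANSION)
        if bad:
            raise ValueError(f"{self.accession}: invalid characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)


class ReferenceDatabase:
    """Ordered collection of reference records, unique by accession."""

    def __init__(self, records: list[ReferenceRecord] | None = None):
        self._records: list[ReferenceRecord] = []
        self._by_accession: dict[str, ReferenceRecord] = {}
        for rec in records or []:
            self.add(rec)

    def add(self, record: ReferenceRecord) -> None:
        if record.accession in self._by_accession:
            raise ValueError(f"duplicate accession: {record.accession}")
        self._records.append(record)
        self._by_accession[record.accession] = record

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def __getitem__(self, accession: str) -> ReferenceRecord:
        return self._by_accession[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self._records:
            seen.setdefault(rec.species, None)
        return list(seen)

    def records_for_species(self, species: str) -> list[ReferenceRecord]:
        return [r for r in self._records if r.species == species]

    def to_files(self, fasta_path, taxonomy_path) -> None:
        seq_records = [
            SeqRecord(Seq(r.sequence), id=r.accession, description="")
            for r in self._records
        ]
        SeqIO.write(seq_records, str(fasta_path), "fasta")
        with open(taxonomy_path, "w") as fh:
            fh.write("accession\tspecies\thigher_taxon\tsource\n")
            for r in self._records:
                fh.write(f"{r.accession}\t{r.species}\t{r.higher_taxon}\t{r.source}\n")


def _check_fasta_format(fasta_path) -> None:
    with open(fasta_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{fasta_path}: line {lineno}: expected FASTA header, "
                    f"got {stripped[:30]!r}"
                )
            return
    raise ValueError(f"{fasta_path}: empty FASTA file")


def load_reference_db(fasta_path, taxonomy_path) -> ReferenceDatabase:
    """Load references from FASTA plus a tab-delimited taxonomy table.

    The taxonomy table has a header line and columns
    ``accession, species[, higher_taxon[, source]]``.  Every FASTA record
    must resolve to a taxonomy row by its header accession (the first
    whitespace-delimited token); a missing row or a duplicated accession is
    a hard error.
    """
    _check_fasta_format(fasta_path)
    taxonomy: dict[str, tuple[str, str, str]] = {}
    with open(taxonomy_path) as fh:
        header = fh.readline()
        if not header.lower().startswith("accession"):
            raise ValueError(f"{taxonomy_path}: missing 'accession' header line")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            acc = parts[0]
            species = parts[1] if len(parts) > 1 else ""
            higher = parts[2] if len(parts) > 2 else ""
            source = parts[3] if len(parts) > 3 else "fixture"
            taxonomy[acc] = (species, higher, source)
    db = ReferenceDatabase()
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        acc = seq_rec.id
        if acc not in taxonomy:
            raise ValueError(f"no taxonomy row for accession {acc!r}")
        species, higher, source = taxonomy[acc]
        db.add(ReferenceRecord(acc, species, higher, str(seq_rec.seq), source))
    return db


@dataclass(frozen=True)
class AmpliconOtu:
    """References sharing a byte-identical amplicon for one assay."""

    otu_id: str
    member_accessions: tuple[str, ...]
    species_set: frozenset[str]
    amplicon_sequence: str
    contains_n: bool = False

    @property
    def n_members(self) -> int:
        return len(self.member_accessions)

    @property
    def is_single_species(self) -> bool:
        return len(self.species_set) == 1


def collapse_amplicon_otus(
    database,
    assay: AssayDefinition,
    max_mismatch: int = 0,
    region: str = "full",
) -> tuple[list[AmpliconOtu], list[str]]:
    """Partition amplifiable references by exact amplicon identity.

    ``region`` selects the sequence the partition is keyed on:
    ``"full"`` (primer-inclusive, the convention amplicon sizes are quoted
    in) or ``"insert"`` (primer-free; the region a primer-trimmed read
    covers, hence the key used by exact-match read assignment).

    Returns ``(otus, non_amplifiable_accessions)``; records with no
    in-silico amplicon are reported, never silently dropped.  Records whose
    amplicon contains N are kept and flagged: under exact string matching
    they can never equal an error-free read, which is the intended
    conservative behaviour.
    """
    if region not in ("full", "insert"):
        raise ValueError(f"region must be 'full' or 'insert', got {region!r}")
    groups: dict[str, list[ReferenceRecord]] = {}
    non_amplifiable: list[str] = []
    for rec in database:
        hits = find_amplicons(assay, rec, max_mismatch=max_mismatch)
        if not hits:
            non_amplifiable.append(rec.accession)
            continue
        amp = hits[0]
        key = amp.sequence if region == "full" else amp.insert
        groups.setdefault(key, []).append(rec)
    otus = []
    for i, (seq, members) in enumerate(sorted(groups.items()), start=1):
        otus.append(
            AmpliconOtu(
                otu_id=f"{assay.name}_OTU_{i:04d}",
                member_accessions=tuple(m.accession for m in members),
                species_set=frozenset(m.species for m in members),
                amplicon_sequence=seq,
                contains_n="N" in seq,
            )
        )
    return otus, non_amplifiable


def write_otu_report(otus: list[AmpliconOtu], path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tn_members\taccessions\tspecies\n")
        for otu in otus:
            fh.write(
                f"{otu.otu_id}\t{otu.n_members}\t"
                f"{','.join(otu.member_accessions)}\t"
                f"{','.join(sorted(otu.species_set))}\n"
            )


# ---------------------------------------------------------------------------
# Synthetic reference database
# ---------------------------------------------------------------------------

#: The eleven mock-community species (three sphaeriid clams, other molluscs,
#: and walleye as the non-target fish) with their higher taxa.
MOCK_SPECIES_TAXA: dict[str, str] = {
    "Sphaerium similie": "Sphaeriidae",
    "Dreissena rostriformis": "Dreissenidae",
    "Sander vitreus": "Percidae",
    "Sphaerium corneum": "Sphaeriidae",
    "Pisidium compressum": "Sphaeriidae",
    "Mytilopsis leucophaeata": "Dreissenidae",
    "Dreissena polymorpha": "Dreissenidae",
    "Potamopyrgus antipodarum": "Tateidae",
    "Gillia altilis": "Lithoglyphidae",
    "Cipangopaludina chinensis": "Viviparidae",
    "Melanoides tuberculata": "Thiaridae",
}

SPHAERIID_SPECIES = frozenset(
    s for s, fam in MOCK_SPECIES_TAXA.items() if fam == "Sphaeriidae"
)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _realize(primer: str, rng: np.random.Generator) -> str:
    """Resolve degenerate positions of a primer to concrete bases."""
    return "".join(
        c if c in "ACGT" else rng.choice(sorted(IUPAC_EXPANSION[c])) for c in primer
    )


def synthetic_reference_database(
    species: dict[str, str] | None = None,
    seed: int = 0,
    insert_length_range: tuple[int, int] = (149, 276),
    sph_insert_length: int = 259,
    pad: int = 20,
) -> ReferenceDatabase:
    """Fabricate a reference database emulating the mock-community taxa.

    Every species gets one synthetic 16S-like template carrying an exact
    (concretely realised) MOL16S forward/reverse primer site around a
    random species-specific insert, so MOL16S amplifies everything.
    Sphaeriid species additionally carry an exact SPH16S site in a second
    region, so SPH16S amplifies only the clams.  Insert lengths span the
    183-310 bp primer-inclusive amplicon range of the broad assay; the
    sphaeriid amplicon is fixed at 299 bp.  Accessions are synthetic
    (``SYN0001``...).
    """
    species = dict(species or MOCK_SPECIES_TAXA)
    rng = np.random.default_rng(seed)
    mol = mol16s_assay()
    sph = sph16s_assay()
    db = ReferenceDatabase()
    for i, (name, higher) in enumerate(species.items(), start=1):
        ins_len = int(rng.integers(insert_length_range[0], insert_length_range[1] + 1))
        fwd = _realize(mol.forward_primer, rng)
        rev = _realize(mol.reverse_primer, rng)
        parts = [
            _random_seq(rng, pad),
            fwd,
            _random_seq(rng, ins_len),
            reverse_complement(rev),
            _random_seq(rng, pad),
        ]
        if name in SPHAERIID_SPECIES or higher == "Sphaeriidae":
            parts += [
                sph.forward_primer,
                _random_seq(rng, sph_insert_length),
                reverse_complement(sph.reverse_primer),
                _random_seq(rng, pad),
            ]
        db.add(
            ReferenceRecord(
                accession=f"SYN{i:04d}",
                species=name,
                higher_taxon=higher,
                sequence="".join(parts),
                source="generated",
            )
        )
    return db
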