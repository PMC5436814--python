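"""Loaders for the packaged benchmark tables.

These are the published per-sample read counts and per-OTU ledgers the
reporting and statistics layers are validated against: mock-community read
counts for both assays, the with/without-blocking-primer comparison, the
aquarium-sample OTU tables, and the negative-control (blank) OTU ledger.
Counts are data inputs here; all percentages are recomputed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("amplimock.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def mock_read_counts(assay: str) -> pd.DataFrame:
    """Per-species read counts of the sequenced mock-community samples.

    ``assay`` is ``"MOL16S"`` (all five communities, run with the fish
    blocking primer) or ``"SPH16S"`` (communities 1, 2 and 4; only the
    three sphaeriid species yielded reads).  Columns:
    community, species, reads.
    """
    name = {"MOL16S": "mol16s_mock_reads.tsv", "SPH16S": "sph16s_mock_reads.tsv"}.get(
        assay.upper()
    )
    if name is None:
        raise KeyError(f"no packaged mock read counts for assay {assay!r}")
    df = _load(name)
    df["community"] = df["community"].astype(str)
    return df


def blocking_comparison() -> pd.DataFrame:
    """Read counts with and without the fish blocking primer.

    Covers replicate runs of mock communities 3 and 4 plus a preliminary
    trial mixture with a high walleye share.  Columns: sample, species,
    reads_with_block, reads_without_block.
    """
    return _load("blocking_comparison.tsv")


def aquaria_otu_table() -> pd.DataFrame:
    """Species-level (>=97% identity) OTU ledger of the aquarium samples.

    One row per best-hit accession; ``identity`` is kept verbatim as
    printed (may be a range like ``98-99``).  Columns: sample, accession,
    species, reads, identity, coverage.
    """
    return _load("aquaria_otus.tsv")


def blank_otu_table() -> pd.DataFrame:
    """OTU ledger of the filtered-water negative control (blank) sample."""
    return _load("blank_otus.tsv")
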