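"""Mock communities: known target-amplicon copy numbers per species, and the
assay-conditional expected read fractions they imply.

A mock community mixes DNA extractions so that each species contributes a
known number of target-amplicon copies per reaction.  If sequencing were
unbiased, the fraction of reads from an amplifiable species would equal its
share of copies among all amplifiable species; that share is the
"expected" percentage the observed read percentages are validated against.
The denominator is conditional on the assay: a group-specific assay only
counts copies from species it amplifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable

import pandas as pd


@dataclass(frozen=True)
class MockCommunity:
    community_id: str
    copies: dict[str, int]

    def __post_init__(self) -> None:
        if not any(c > 0 for c in self.copies.values()):
            raise ValueError(f"community {self.community_id}: all copy numbers zero")
        if any(c < 0 for c in self.copies.values()):
            raise ValueError(f"community {self.community_id}: negative copy number")

    @property
    def species(self) -> list[str]:
        return list(self.copies)


def _packaged_table(name: str) -> pd.DataFrame:
    with resources.files("amplimock.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def builtin_communities() -> list[MockCommunity]:
    """The five packaged mock-community recipes (copies per extraction)."""
    df = _packaged_table("mock_communities.tsv")
    out = []
    for cid, grp in df.groupby("community", sort=True):
        out.append(
            MockCommunity(str(cid), dict(zip(grp["species"], grp["copies"].astype(int))))
        )
    return out


def get_community(community_id: str | int) -> MockCommunity:
    for c in builtin_communities():
        if c.community_id == str(community_id):
            return c
    raise KeyError(f"no builtin mock community {community_id!r}")


def expected_fractions(
    community: MockCommunity,
    amplifiable: Callable[[str], bool] | Iterable[str] | None = None,
) -> dict[str, float]:
    """Expected read percentage per species, conditional on amplifiability.

    ``amplifiable`` is a predicate (or a collection) naming the species the
    assay amplifies; ``None`` means all.  Amplifiable species get
    ``100 * copies / sum(copies over amplifiable species)``; non-amplifiable
    species get 0.  Raises ``ValueError`` when no amplifiable species has
    copies.
    """
    if amplifiable is None:
        pred = lambda s: True  # noqa: E731
    elif callable(amplifiable):
        pred = amplifiable
    else:
        allowed = set(amplifiable)
        pred = lambda s: s in allowed  # noqa: E731
    denom = sum(c for s, c in community.copies.items() if pred(s))
    if denom <= 0:
        raise ValueError(
            f"community {community.community_id}: no amplifiable species with copies"
        )
    return {
        s: (100.0 * c / denom if pred(s) else 0.0) for s, c in community.copies.items()
    }


def expected_fraction_table(
    community: MockCommunity,
    amplifiable: Callable[[str], bool] | Iterable[str] | None = None,
) -> pd.DataFrame:
    fracs = expected_fractions(community, amplifiable)
    return pd.DataFrame(
        {
            "species": list(community.copies),
            "copies": list(community.copies.values()),
            "pct_expected": [fracs[s] for s in community.copies],
        }
    )
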