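"""Paired-end amplicon read simulator with per-read ground truth.

Emulates what the two-step library construct looks like to the sequencer:
each template contributes a construct

    [forward spacer][forward primer site][insert][revcomp reverse primer
    site][revcomp reverse spacer]

read from both ends (read 1 = construct 5'->3', read 2 = reverse
complement), with per-base substitution errors, a cycle-dependent quality
model, PCR chimeras spliced from two parent inserts, and a configurable
fraction of non-sample decoy pairs standing in for the PhiX spike-in /
unindexed reads.  Template choice per pair is multinomial with weight

    copies x efficiency_bias x (1 - blocking_efficiency if blocked)

so amplification bias and blocking-primer suppression act on the
*observed* composition while the community recipe still defines the
*expected* one.  A truth table records provenance of every pair, making
every downstream stage testable without a sequencer.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .assays import AssayDefinition, find_amplicons
from .communities import MockCommunity
from .iupac import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    r1_sequence: str
    r1_quality: str
    r2_sequence: str
    r2_quality: str


@dataclass
class SimulationConfig:
    """Everything one simulated sample depends on.

    ``error_rate`` is the per-base substitution probability (uniform over
    the three alternative bases).  The quality model is a linear mean-Q
    decay along the cycle (``q_start`` at cycle 0, minus ``q_decay`` per
    cycle) with Gaussian jitter of SD ``q_jitter``, clipped to [2, 41].
    ``efficiency_bias`` multiplies a species' template weight; if
    ``bias_lognormal_sigma`` > 0 and no explicit bias is given, per-species
    biases are drawn lognormally to emulate amplification over/under-
    representation.  ``blocking_efficiency`` is the fraction of blocked-
    species templates suppressed by the blocking primer.
    """

    assay: AssayDefinition
    community: MockCommunity
    refdb: object
    n_read_pairs: int
    read_length: int = 300
    error_rate: float = 0.0
    q_start: float = 38.0
    q_decay: float = 0.02
    q_jitter: float = 2.0
    chimera_rate: float = 0.0
    efficiency_bias: dict[str, float] | None = None
    bias_lognormal_sigma: float = 0.0
    blocking_efficiency: float = 0.0
    blocked_species: frozenset[str] = frozenset()
    phix_fraction: float = 0.0
    spacer_set: str = "E"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate", "chimera_rate", "blocking_efficiency", "phix_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_read_pairs <= 0:
            raise ValueError("n_read_pairs must be positive")
        if self.spacer_set not in self.assay.spacer_sets:
            raise ValueError(f"unknown spacer set {self.spacer_set!r}")


@dataclass
class SimulationResult:
    pairs: list[ReadPair]
    truth: pd.DataFrame  # read_id, species, accession, chimera, decoy

    def write_fastq(self, r1_path, r2_path) -> None:
        for path, which in ((r1_path, "r1"), (r2_path, "r2")):
            opener = gzip.open if str(path).endswith(".gz") else open
            with opener(str(path), "wt") as fh:
                for p in self.pairs:
                    seq = p.r1_sequence if which == "r1" else p.r2_sequence
                    qual = p.r1_quality if which == "r1" else p.r2_quality
                    fh.write(f"@{p.read_id}\n{seq}\n+\n{qual}\n")


def _phred_string(q: np.ndarray) -> str:
    return (q.astype(np.uint8) + 33).tobytes().decode("ascii")


class _QualityModel:
    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng

    def sample(self, length: int) -> np.ndarray:
        mean = self.cfg.q_start - self.cfg.q_decay * np.arange(length)
        q = mean + self.rng.normal(0.0, self.cfg.q_jitter, size=length)
        return np.clip(np.rint(q), 2, 41).astype(np.int16)


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    n = len(seq)
    k = rng.binomial(n, error_rate)
    if k == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    pos = rng.choice(n, size=k, replace=False)
    for p in pos:
        current = arr[p]
        choices = _BASES[_BASES != current]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _template_constructs(cfg: SimulationConfig) -> dict[str, list[tuple[str, str, str]]]:
    """Per species: list of (accession, construct, insert) for amplifiable records."""
    spacers = cfg.assay.spacer_sets[cfg.spacer_set]
    rc_rev_spacer = reverse_complement(spacers.reverse_spacer)
    out: dict[str, list[tuple[str, str, str]]] = {}
    for species in cfg.community.copies:
        entries = []
        for rec in cfg.refdb.records_for_species(species):
            hits = find_amplicons(cfg.assay, rec, max_mismatch=0)
            if hits:
                amp = hits[0]
                construct = spacers.forward_spacer + amp.sequence + rc_rev_spacer
                entries.append((rec.accession, construct, amp.insert))
        out[species] = entries
    return out


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate a simulated paired-end sample plus its truth table.

    Deterministic for a fixed config (byte-identical FASTQ on rerun).
    Species with copies but no amplifiable reference simply contribute no
    templates (they are recorded as non-amplifiable); an error is raised
    only when no species at all can amplify.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    constructs = _template_constructs(cfg)

    bias = dict(cfg.efficiency_bias or {})
    if not bias and cfg.bias_lognormal_sigma > 0:
        for sp in cfg.community.copies:
            bias[sp] = float(rng.lognormal(0.0, cfg.bias_lognormal_sigma))

    species_list, weights = [], []
    non_amplifiable = []
    for sp, copies in cfg.community.copies.items():
        if copies <= 0:
            continue
        if not constructs[sp]:
            non_amplifiable.append(sp)
            continue
        w = copies * bias.get(sp, 1.0)
        if sp in cfg.blocked_species:
            w *= 1.0 - cfg.blocking_efficiency
        if w > 0:
            species_list.append(sp)
            weights.append(w)
    if not species_list:
        raise ValueError(
            "no amplifiable templates in community; non-amplifiable species: "
            + ", ".join(non_amplifiable)
        )
    w = np.asarray(weights, dtype=float)
    probs = w / w.sum()

    n_total = cfg.n_read_pairs
    n_phix = int(round(cfg.phix_fraction * n_total))
    n_templates = n_total - n_phix

    qual = _QualityModel(cfg, rng)
    pairs: list[ReadPair] = []
    truth_rows: list[tuple[str, str, str, bool, bool]] = []

    sp_idx = rng.choice(len(species_list), size=n_templates, p=probs)
    chimera_flags = (
        rng.random(n_templates) < cfg.chimera_rate
        if cfg.chimera_rate > 0
        else np.zeros(n_templates, dtype=bool)
    )

    for i in range(n_templates):
        species = species_list[sp_idx[i]]
        recs = constructs[species]
        acc, construct, insert = recs[rng.integers(len(recs))] if len(recs) > 1 else recs[0]
        is_chimera = bool(chimera_flags[i])
        if is_chimera and len(species_list) > 1:
            j = int(rng.integers(len(species_list)))
            other = constructs[species_list[j]]
            acc2, _, insert2 = other[rng.integers(len(other))] if len(other) > 1 else other[0]
            # splice the two inserts at a uniform interior breakpoint and
            # rebuild the construct around the hybrid insert
            k1 = int(rng.integers(1, len(insert)))
            k2 = int(rng.integers(1, len(insert2)))
            hybrid = insert[:k1] + insert2[k2:]
            head_len = len(cfg.assay.spacer_sets[cfg.spacer_set].forward_spacer) + len(
                cfg.assay.forward_primer
            )
            head = construct[:head_len]
            tail = construct[head_len + len(insert):]
            construct = head + hybrid + tail
            acc = f"{acc}|{acc2}"
        else:
            is_chimera = False
        L = min(cfg.read_length, len(construct))
        r1 = _mutate(construct[:L], rng, cfg.error_rate)
        r2 = _mutate(reverse_complement(construct)[:L], rng, cfg.error_rate)
        rid = f"sim_{i:07d}|{species.replace(' ', '_')}|{acc}|chimera={int(is_chimera)}"
        pairs.append(
            ReadPair(
                rid,
                r1,
                _phred_string(qual.sample(len(r1))),
                r2,
                _phred_string(qual.sample(len(r2))),
            )
        )
        truth_rows.append((rid, species, acc, is_chimera, False))

    for i in range(n_phix):
        L = cfg.read_length
        seq1 = _BASES[rng.integers(0, 4, size=L)].tobytes().decode("ascii")
        seq2 = _BASES[rng.integers(0, 4, size=L)].tobytes().decode("ascii")
        rid = f"phix_{i:07d}|decoy"
        pairs.append(
            ReadPair(
                rid,
                seq1,
                _phred_string(qual.sample(L)),
                seq2,
                _phred_string(qual.sample(L)),
            )
        )
        truth_rows.append((rid, "", "", False, True))

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "species", "accession", "chimera", "decoy"]
    )
    truth.attrs["non_amplifiable_species"] = non_amplifiable
    return SimulationResult(pairs=pairs, truth=truth)


def truth_fractions(truth: pd.DataFrame) -> dict[str, float]:
    """Percent of template-derived (non-decoy) pairs per source species."""
    templates = truth[~truth["decoy"]]
    n = len(templates)
    if n == 0:
        return {}
    counts = templates["species"].value_counts()
    return {sp: 100.0 * c / n for sp, c in counts.items()}
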