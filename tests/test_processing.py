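"""Pair merging, construct trimming and retention filters with stage
conservation."""

import pytest
from hypothesis import given, settings, strategies as st

from amplimock.assays import SPACER_SETS
from amplimock.iupac import reverse_complement
from amplimock.processing import (
    Read,
    merge_pairs,
    retention_filters,
    trim_construct,
)
from amplimock.simulate import ReadPair, SimulationConfig, simulate
from amplimock.communities import MockCommunity


def _pair_from_template(template, read_len, rid="p1", q="I"):
    r1 = template[:read_len]
    r2 = reverse_complement(template)[:read_len]
    return ReadPair(rid, r1, q * len(r1), r2, q * len(r2))


class TestMerge:
    def test_error_free_pair_reconstructs_template(self):
        rng = __import__("numpy").random.default_rng(12)
        template = "".join(rng.choice(list("ACGT"), size=400))  # 2 x 300 reads
        pair = _pair_from_template(template, 300)
        merged, acct = merge_pairs([pair])
        assert len(merged) == 1
        assert merged[0].sequence == template
        assert acct.conserved and acct.n_out == 1

    def test_disagreement_takes_higher_quality_base_and_lower_quality(self):
        rng = __import__("numpy").random.default_rng(21)
        template = "".join(rng.choice(list("ACGT"), size=120))
        r1 = template
        r2rc = template[:60] + ("G" if template[60] != "G" else "T") + template[61:]
        q_hi, q_lo = chr(40 + 33), chr(10 + 33)
        pair = ReadPair(
            "d1",
            r1,
            q_hi * len(r1),
            reverse_complement(r2rc),
            q_lo * len(r2rc),
        )
        merged, _ = merge_pairs([pair])
        assert merged[0].sequence == template  # r1's base wins (Q40 vs Q10)
        assert merged[0].quality[60] == q_lo  # disagreement keeps the lower Q

    def test_agreement_quality_is_capped_max(self):
        rng = __import__("numpy").random.default_rng(22)
        template = "".join(rng.choice(list("ACGT"), size=120))
        q = chr(40 + 33)
        pair = ReadPair("a1", template, q * 120, reverse_complement(template), q * 120)
        merged, _ = merge_pairs([pair])
        assert max(ord(c) - 33 for c in merged[0].quality) <= 41

    def test_non_overlapping_pair_rejected_with_reason(self):
        pair = ReadPair("n1", "ACGTAGGCCTTA" * 10, "I" * 120, "TTTTGGGGAAAA" * 10, "I" * 120)
        merged, acct = merge_pairs([pair])
        assert merged == []
        assert acct.n_rejected_by_reason.get("no_overlap", 0) + acct.n_rejected_by_reason.get(
            "mismatch_rate", 0
        ) == 1
        assert acct.conserved


FWD = "AGTAGACGAGAAGACCCT"  # concrete MOL16S forward site
REV = "AATCCAACATCGAGGT"  # concrete MOL16S reverse site


def _merged_read(spacer_set, insert, rid="m1"):
    s = SPACER_SETS[spacer_set]
    seq = (
        s.forward_spacer
        + FWD
        + insert
        + reverse_complement(REV)
        + reverse_complement(s.reverse_spacer)
    )
    return Read(rid, seq, "I" * len(seq))


class TestTrim:
    @pytest.mark.parametrize("spacer_set", ["E", "F", "G", "H"])
    def test_exact_primers_trim_to_insert_for_every_spacer_set(self, mol16s, spacer_set):
        insert = "TTGACA" * 30
        read = _merged_read(spacer_set, insert)
        inserts, acct = trim_construct([read], mol16s)
        assert len(inserts) == 1
        assert inserts[0].sequence == insert
        assert acct.conserved

    def test_missing_reverse_primer_rejected(self, mol16s):
        s = SPACER_SETS["E"]
        seq = s.forward_spacer + FWD + "TTGACA" * 30
        inserts, acct = trim_construct([Read("r", seq, "I" * len(seq))], mol16s)
        assert inserts == []
        assert acct.n_rejected_by_reason == {"no_reverse_primer": 1}

    def test_forward_mismatch_needs_budget(self, mol16s):
        insert = "TTGACA" * 30
        mutated = "C" + FWD[1:]
        s = SPACER_SETS["E"]
        seq = (
            s.forward_spacer
            + mutated
            + insert
            + reverse_complement(REV)
            + reverse_complement(s.reverse_spacer)
        )
        read = Read("mm", seq, "I" * len(seq))
        kept0, acct0 = trim_construct([read], mol16s, max_primer_mismatch=0)
        assert kept0 == [] and acct0.n_rejected_by_reason == {"no_forward_primer": 1}
        kept1, _ = trim_construct([read], mol16s, max_primer_mismatch=1)
        assert len(kept1) == 1 and kept1[0].sequence == insert

    def test_interior_primer_match_does_not_trigger_trimming(self, mol16s):
        # bury a full construct deep inside a read: the anchored search
        # must not trim at the interior site
        insert = "TTGACA" * 30
        interior = FWD + insert + reverse_complement(REV)
        seq = "GATC" * 20 + interior + "GATC" * 20
        inserts, acct = trim_construct([Read("deep", seq, "I" * len(seq))], mol16s)
        assert inserts == []
        assert acct.n_in == 1 and acct.conserved


class TestRetention:
    def test_length_boundary_is_inclusive_at_100(self):
        reads = [
            Read("short", "A" * 99, "I" * 99),
            Read("exact", "C" * 100, "I" * 100),
            Read("exact2", "C" * 100, "I" * 100),
        ]
        kept, acct = retention_filters(reads, min_length=100, drop_singletons=False)
        assert [r.read_id for r in kept] == ["exact", "exact2"]
        assert acct.n_rejected_by_reason == {"short": 1}

    def test_singleton_removal_by_exact_multiplicity(self):
        seqs = ["A" * 120] * 3 + ["C" * 120] * 1 + ["G" * 120] * 2
        reads = [Read(f"r{i}", s, "I" * len(s)) for i, s in enumerate(seqs)]
        kept, acct = retention_filters(reads, drop_singletons=True)
        assert len(kept) == 5
        assert acct.n_rejected_by_reason == {"singleton": 1}
        assert all(r.sequence != "C" * 120 for r in kept)

    @given(
        st.lists(
            st.tuples(st.sampled_from(["AAA", "CCC", "GGG", "TTT"]), st.integers(1, 5)),
            max_size=6,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_conservation_holds_for_arbitrary_multisets(self, spec):
        reads = []
        i = 0
        for seq3, mult in spec:
            seq = seq3 * 40  # 120 bp
            for _ in range(mult):
                reads.append(Read(f"r{i}", seq, "I" * len(seq)))
                i += 1
        kept, acct = retention_filters(reads)
        assert acct.n_in == len(reads)
        assert acct.conserved
        assert acct.n_out == len(kept)


class TestEndToEndRecovery:
    def test_merge_then_trim_recovers_all_inserts_on_error_free_reads(
        self, mol16s, refdb
    ):
        community = MockCommunity(
            "mini", {"Sphaerium similie": 500, "Gillia altilis": 500}
        )
        cfg = SimulationConfig(
            assay=mol16s, community=community, refdb=refdb, n_read_pairs=2000, seed=6
        )
        sim = simulate(cfg)
        merged, acct_m = merge_pairs(sim.pairs)
        inserts, acct_t = trim_construct(merged, mol16s)
        assert acct_m.n_out == acct_t.n_in == acct_t.n_out == 2000
        from amplimock.refdb import collapse_amplicon_otus

        otus, _ = collapse_amplicon_otus(refdb, mol16s, region="insert")
        valid = {o.amplicon_sequence for o in otus}
        assert all(r.sequence in valid for r in inserts)
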