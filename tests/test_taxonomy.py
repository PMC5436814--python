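"""Exact-match assignment, greedy OTU clustering and local-alignment
identification."""

import numpy as np
import pytest

from amplimock.refdb import (
    ReferenceDatabase,
    ReferenceRecord,
    collapse_amplicon_otus,
    synthetic_reference_database,
)
from amplimock.simulate import SimulationConfig, simulate
from amplimock.processing import merge_pairs, trim_construct
from amplimock.taxonomy import (
    OtuCluster,
    assign_exact,
    cluster_otus,
    global_identity,
    identify_otus,
    local_alignment_stats,
    report_composition,
)

from oracles import gotoh_local


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestAssignExact:
    def test_exact_read_counts_for_its_species(self, mol16s, refdb):
        otus, _ = collapse_amplicon_otus(refdb, mol16s, region="insert")
        single = next(o for o in otus if o.is_single_species)
        result = assign_exact([single.amplicon_sequence], otus)
        sp = next(iter(single.species_set))
        assert result.species_counts == {sp: 1}
        assert result.n_unassigned == 0

    def test_one_substitution_is_unassigned(self, mol16s, refdb):
        otus, _ = collapse_amplicon_otus(refdb, mol16s, region="insert")
        seq = otus[0].amplicon_sequence
        mutated = seq[:5] + ("A" if seq[5] != "A" else "C") + seq[6:]
        result = assign_exact([mutated], otus)
        assert result.n_unassigned == 1
        assert result.species_counts == {}

    def test_multi_species_otu_counts_as_ambiguous(self):
        from amplimock.refdb import AmpliconOtu

        otu = AmpliconOtu("X", ("A1", "A2"), frozenset({"Sp a", "Sp b"}), "ACGT" * 30)
        result = assign_exact(["ACGT" * 30] * 3, [otu])
        assert result.ambiguous_assignments == {"X": 3}
        assert result.n_assigned == 0
        assert result.conserved

    def test_simulated_low_error_sample_tracks_truth_oracle(self, mol16s, refdb, communities):
        cfg = SimulationConfig(
            assay=mol16s,
            community=communities["1"],
            refdb=refdb,
            n_read_pairs=20000,
            error_rate=0.003,
            seed=8,
        )
        sim = simulate(cfg)
        merged, _ = merge_pairs(sim.pairs)
        inserts, _ = trim_construct(merged, mol16s)
        otus, _ = collapse_amplicon_otus(refdb, mol16s, region="insert")
        result = assign_exact(inserts, otus)
        assert result.conserved
        # brute-force oracle: a read is assigned iff its trimmed insert is
        # error-free, i.e. equals its source species' reference insert
        reference_insert = {
            next(iter(o.species_set)): o.amplicon_sequence for o in otus
        }
        source = dict(zip(sim.truth["read_id"], sim.truth["species"]))
        expected_counts: dict[str, int] = {}
        for read in inserts:
            sp = source[read.read_id]
            if read.sequence == reference_insert[sp]:
                expected_counts[sp] = expected_counts.get(sp, 0) + 1
        assert result.species_counts == expected_counts
        assert result.n_assigned == sum(expected_counts.values())


class TestClusterOtus:
    def test_minor_variant_joins_abundant_centroid(self):
        rng = np.random.default_rng(0)
        base = _rand_seq(rng, 300)
        variant = base[:150] + ("A" if base[150] != "A" else "C") + base[151:]
        reads = [base] * 100 + [variant] * 5
        clusters = cluster_otus(reads)
        assert len(clusters) == 1
        assert clusters[0].representative == base
        assert clusters[0].read_count == 105

    def test_diverged_sequences_found_separate_otus(self):
        rng = np.random.default_rng(1)
        a = _rand_seq(rng, 300)
        # mutate 10% of positions -> ~90% identity, below the 97% threshold
        b = list(a)
        pos = rng.choice(300, size=30, replace=False)
        for p in pos:
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        b = "".join(b)
        assert global_identity(a, b) < 97.0
        clusters = cluster_otus([a] * 10 + [b] * 10)
        assert len(clusters) == 2

    def test_clustering_partitions_reads(self):
        rng = np.random.default_rng(2)
        reads = []
        for _ in range(4):
            s = _rand_seq(rng, 250)
            reads += [s] * int(rng.integers(1, 10))
        clusters = cluster_otus(reads)
        assert sum(c.read_count for c in clusters) == len(reads)

    def test_threshold_one_equals_exact_deduplication(self):
        rng = np.random.default_rng(3)
        uniq = [_rand_seq(rng, 200) for _ in range(5)]
        near = uniq[0][:100] + ("A" if uniq[0][100] != "A" else "C") + uniq[0][101:]
        reads = uniq * 3 + [near]
        clusters = cluster_otus(reads, threshold=1.0)
        assert len(clusters) == len(set(reads))
        counts = sorted(c.read_count for c in clusters)
        assert counts == sorted([3] * 5 + [1])

    def test_well_separated_species_give_exactly_k_otus(self, mol16s, refdb, communities):
        cfg = SimulationConfig(
            assay=mol16s,
            community=communities["1"],
            refdb=refdb,
            n_read_pairs=3000,
            seed=11,
        )
        sim = simulate(cfg)
        merged, _ = merge_pairs(sim.pairs)
        inserts, _ = trim_construct(merged, mol16s)
        clusters = cluster_otus(inserts)
        k = sim.truth["species"].nunique()
        assert len(clusters) == k


class TestLocalIdentification:
    def test_identity_and_coverage_agree_with_quadratic_oracle(self):
        """Substitution-only and clean-indel instances up to 400 bp."""
        rng = np.random.default_rng(4)
        cases = []
        for qlen in (120, 250, 400):
            subject = _rand_seq(rng, qlen + 100)
            query = subject[50 : 50 + qlen]
            # plant up to 3 substitutions
            q = list(query)
            for p in rng.choice(qlen, size=3, replace=False):
                q[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[p]]
            cases.append(("".join(q), subject))
        # one clean deletion in the query
        subject = _rand_seq(rng, 300)
        cases.append((subject[20:150] + subject[160:280], subject))
        for query, subject in cases:
            ident, cov = local_alignment_stats(query, subject)
            _, o_ident, o_cov = gotoh_local(query, subject)
            assert ident == pytest.approx(o_ident, abs=1e-9)
            assert cov == pytest.approx(o_cov, abs=1e-9)

    def test_identical_representative_scores_100_100(self, refdb):
        rec = next(iter(refdb))
        ident, cov = local_alignment_stats(rec.sequence, rec.sequence)
        assert ident == 100.0 and cov == 100.0

    def test_divergent_representative_below_species_threshold(self):
        rng = np.random.default_rng(5)
        ref_seq = _rand_seq(rng, 300)
        q = list(ref_seq)
        for p in rng.choice(300, size=15, replace=False):  # ~95% identity
            q[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[p]]
        query = "".join(q)
        db = ReferenceDatabase([ReferenceRecord("R1", "Ref species", "F", ref_seq)])
        clusters = [OtuCluster("OTU_0001", query, 10, [query], [10])]
        records, acct = identify_otus(clusters, db)
        assert len(records) == 1
        rec = records[0]
        assert rec.coverage_pct >= 80.0
        assert rec.identity_pct < 97.0
        assert not rec.species_level

    def test_singleton_otu_dropped_with_reason(self, refdb):
        rec = next(iter(refdb))
        clusters = [OtuCluster("OTU_0001", rec.sequence[:150], 1, [], [])]
        records, acct = identify_otus(clusters, refdb)
        assert records == []
        assert acct.n_rejected_by_reason == {"singleton_otu": 1}

    def test_same_accession_hits_are_pooled(self, refdb):
        rec = next(iter(refdb))
        a = rec.sequence[:200]
        b = rec.sequence[10:210]
        clusters = [
            OtuCluster("OTU_0001", a, 30, [a], [30]),
            OtuCluster("OTU_0002", b, 12, [b], [12]),
        ]
        records, _ = identify_otus(clusters, refdb)
        pooled = [r for r in records if r.best_hit_accession == rec.accession]
        assert len(pooled) == 1
        assert pooled[0].read_count == 42


class TestReportComposition:
    def test_published_tank_ledger_species_level_percentages(self):
        from amplimock.tables import aquaria_otu_table

        table = aquaria_otu_table()
        tank_a = table[table["sample"] == "MOL16S_tank_A"]
        report = report_composition(tank_a)
        top = report.loc[
            (report["accession"] == "AF152045"), "pct_species_level"
        ].iloc[0]
        assert round(top, 3) == 86.737

    def test_single_record_is_100_percent(self):
        import pandas as pd

        df = pd.DataFrame(
            [{"accession": "X1", "species": "Sp", "reads": 50, "identity": "99"}]
        )
        report = report_composition(df)
        assert report["pct_species_level"].iloc[0] == 100.0

    def test_species_level_percentages_sum_to_100(self):
        from amplimock.tables import aquaria_otu_table

        table = aquaria_otu_table()
        for sample, grp in table.groupby("sample"):
            report = report_composition(grp)
            assert report.loc[report.species_level, "pct_species_level"].sum() == pytest.approx(
                100.0, abs=1e-9
            )
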