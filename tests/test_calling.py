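"""Clustering, consensus, chimera screening, catalog validation, genotyping."""

import pytest

from mhctyper import simulate as sim
from mhctyper.calling import (
    Contig,
    build_catalog,
    call_consensus,
    call_genotypes,
    cluster_reads,
    flag_chimeras,
    genotype_individuals,
    qc_individuals,
)


def _mutate(seq, pos, base):
    return seq[:pos] + base + seq[pos + 1 :]


def _other(base):
    return "A" if base != "A" else "G"


class TestClusterReads:
    def test_identical_reads_one_contig(self, small_pool):
        seq = small_pool.alleles[0][1]
        contigs = cluster_reads([seq] * 50)
        assert len(contigs) == 1
        assert contigs[0].depth == 50
        assert contigs[0].consensus == seq

    def test_single_read(self, small_pool):
        seq = small_pool.alleles[0][1]
        contigs = cluster_reads([seq])
        assert len(contigs) == 1
        assert contigs[0].depth == 1
        assert contigs[0].consensus == seq

    def test_empty_input(self):
        assert cluster_reads([]) == []

    def test_one_nt_apart_alleles_separate(self, small_pool):
        """Alleles differing at a single site must yield two clean contigs
        when both are deeply represented (0.36% < the 2% mismatch ceiling)."""
        a = small_pool.alleles[0][1]
        b = _mutate(a, 150, _other(a[150]))
        contigs = cluster_reads([a] * 200 + [b] * 200)
        consensi = {c.consensus for c in contigs}
        assert a in consensi and b in consensi
        for c in contigs:
            assert not c.ambiguous_sites

    def test_errored_reads_join_template_cluster(self, small_pool):
        a = small_pool.alleles[0][1]
        noisy = [_mutate(a, i, _other(a[i])) for i in (3, 50, 100)]
        contigs = cluster_reads([a] * 30 + noisy)
        assert len(contigs) == 1
        assert contigs[0].depth == 33
        assert contigs[0].consensus == a

    def test_every_read_in_exactly_one_contig(self, small_pool):
        a, b = small_pool.alleles[0][1], small_pool.alleles[1][1]
        reads = [a] * 20 + [b] * 15 + [_mutate(a, 9, _other(a[9]))] * 2
        contigs = cluster_reads(reads)
        assert sum(c.depth for c in contigs) == len(reads)


class TestCallConsensus:
    def test_threshold_boundaries(self):
        col_pass = ["A"] * 8 + ["G"] * 2    # 0.80 >= 0.75
        col_fail = ["A"] * 7 + ["G"] * 3    # 0.70 < 0.75
        cons, amb = call_consensus(col_pass, threshold=0.75)
        assert (cons, amb) == ("A", [])
        cons, amb = call_consensus(col_fail, threshold=0.75)
        assert cons == "N" and amb == [0]

    def test_exact_threshold_accepted(self):
        cons, amb = call_consensus(["A"] * 3 + ["G"], threshold=0.75)
        assert (cons, amb) == ("A", [])

    def test_identical_members(self):
        cons, amb = call_consensus(["ACGT"] * 5)
        assert (cons, amb) == ("ACGT", [])


class TestFlagChimeras:
    def _contigs(self, a, b, hybrid, depths):
        return [
            Contig("x", [f"r{i}"] * d, [s] * d, s)
            for (s, d), i in zip(zip((a, b, hybrid), depths), range(3))
        ]

    def test_underrepresented_hybrid_flagged(self, small_pool):
        a, b = small_pool.alleles[0][1], small_pool.alleles[1][1]
        hybrid = a[:150] + b[150:]
        contigs = self._contigs(a, b, hybrid, (100, 80, 10))
        flags = flag_chimeras(contigs)
        assert flags == [False, False, True]
        assert contigs[2].is_chimeric

    def test_deep_hybrid_retained(self, small_pool):
        a, b = small_pool.alleles[0][1], small_pool.alleles[1][1]
        hybrid = a[:150] + b[150:]
        contigs = self._contigs(a, b, hybrid, (100, 80, 90))
        assert flag_chimeras(contigs) == [False, False, False]

    def test_synthetic_run_chimera_recall_and_precision(self, small_run, small_bins):
        """>= 90% of chimeric contigs flagged; no true allele at depth >= 12
        is ever flagged."""
        catalog, table, contigs = call_genotypes(small_bins.assigned)
        pool_seqs = set(small_run["pool"].sequences.values())
        truth = small_run["truth"]
        chimeric_inserts = set()
        seqs = small_run["pool"].sequences
        for row in truth[truth.is_chimera].itertuples():
            a, b = row.source_alleles.split("+")
            chimeric_inserts.add(seqs[a][: row.breakpoint] + seqs[b][row.breakpoint :])
        chimeric_inserts -= pool_seqs  # crossovers identical to a parent are real alleles
        n_chim = n_flagged = 0
        for ind, cs in contigs.items():
            for c in cs:
                if c.consensus in chimeric_inserts:
                    n_chim += 1
                    n_flagged += c.is_chimeric
                if c.consensus in pool_seqs and c.depth >= 12:
                    assert not c.is_chimeric
        assert n_chim > 0
        assert n_flagged / n_chim >= 0.9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            flag_chimeras([])


class TestBuildCatalog:
    def _contig(self, ind, seq, depth):
        return Contig(ind, [f"{ind}r{i}" for i in range(depth)], [seq] * depth, seq)

    def test_two_birds_confirmed(self, small_pool):
        seq = small_pool.alleles[0][1]
        catalog = build_catalog(
            {"b1": [self._contig("b1", seq, 30)], "b2": [self._contig("b2", seq, 25)]}
        )
        (entry,) = catalog.entries.values()
        assert entry.status == "confirmed"
        assert entry.n_individuals == 2
        assert entry.total_reads == 55

    def test_singleton_at_boundary(self, small_pool):
        seq = small_pool.alleles[0][1]
        low = build_catalog({"b1": [self._contig("b1", seq, 11)]})
        assert next(iter(low.entries.values())).status == "rejected_lowdepth"
        ok = build_catalog({"b1": [self._contig("b1", seq, 12)]})
        assert next(iter(ok.entries.values())).status == "provisional"

    def test_singleton_blatantly_underrepresented_rejected(self, small_pool):
        a, b, c = (small_pool.alleles[i][1] for i in range(3))
        contigs = [
            self._contig("b1", a, 200),
            self._contig("b1", b, 180),
            self._contig("b1", c, 20),  # 20 < 0.25 * mean(200, 180)
        ]
        catalog = build_catalog({"b1": contigs})
        by_seq = {e.sequence: e.status for e in catalog.entries.values()}
        assert by_seq[c] == "rejected_lowdepth"
        assert by_seq[a] == by_seq[b] == "provisional"

    def test_stop_codon_allele_quarantined(self):
        pool = sim.generate_allele_pool(3, seed=2, include_stop_allele=True)
        stop_seq = pool.alleles[-1][1]
        catalog = build_catalog(
            {"b1": [self._contig("b1", stop_seq, 30)],
             "b2": [self._contig("b2", stop_seq, 27)]}
        )
        (entry,) = catalog.entries.values()
        assert entry.status == "nonfunctional_stop"

    def test_min_reads_monotonicity(self, small_run, small_bins):
        _, _, contigs = call_genotypes(small_bins.assigned)
        sizes = []
        for mr in (5, 12, 30):
            cat = build_catalog(contigs, min_reads=mr)
            sizes.append(len([e for e in cat.entries.values()
                              if e.status in ("confirmed", "provisional")]))
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_depth_conservation(self, small_bins):
        catalog, table, contigs = call_genotypes(small_bins.assigned)
        total_contig = sum(c.depth for cs in contigs.values() for c in cs)
        total_reads = sum(len(rs) for rs in small_bins.assigned.values())
        assert total_contig == total_reads
        assert sum(e.total_reads for e in catalog.entries.values()) <= total_contig

    def test_catalog_matches_truth_on_synthetic_run(self, small_run, small_bins):
        """Accepted catalog = true alleles sampled at sufficient depth; no
        chimera sequence is catalogued."""
        catalog, _, _ = call_genotypes(small_bins.assigned)
        pool_seqs = set(small_run["pool"].sequences.values())
        accepted = {e.sequence for e in catalog.accepted().values()}
        assert accepted <= pool_seqs


class TestGenotypeAndQC:
    def test_exact_match_required(self, small_pool):
        a = small_pool.alleles[0][1]
        near = _mutate(a, 5, _other(a[5]))
        contigs = {
            "b1": [Contig("b1", ["r1"] * 30, [a] * 30, a)],
            "b2": [Contig("b2", ["r2"] * 30, [a] * 30, a)],
        }
        catalog = build_catalog(contigs)
        contigs["b1"].append(Contig("b1", ["r3"] * 20, [near] * 20, near))
        table = genotype_individuals(contigs, catalog)
        assert len(table.rows["b1"]) == 1
        assert table.unmatched["b1"] == [(near, 20)]

    def test_genotyping_reproducible(self, small_bins):
        cat1, t1, _ = call_genotypes(small_bins.assigned)
        cat2, t2, _ = call_genotypes(small_bins.assigned)
        assert t1.rows == t2.rows
        assert t1.qc == t2.qc
        assert {n: e.sequence for n, e in cat1.entries.items()} == {
            n: e.sequence for n, e in cat2.entries.items()
        }

    def test_qc_read_thresholds(self, small_pool):
        a = small_pool.alleles[0][1]

        def table_with_depth(d):
            contigs = {
                "b1": [Contig("b1", [f"r{i}" for i in range(d)], [a] * d, a)],
                "b2": [Contig("b2", [f"q{i}" for i in range(40)], [a] * 40, a)],
            }
            catalog = build_catalog(contigs)
            return qc_individuals(genotype_individuals(contigs, catalog))

        assert table_with_depth(24).qc["b1"] == "discarded_low_reads"
        assert table_with_depth(25).qc["b1"] == "pass"
        assert table_with_depth(29).qc["b1"] == "pass"

    def test_empty_table(self):
        table = qc_individuals(genotype_individuals({}, build_catalog({})))
        assert table.rows == {}


class TestEndToEnd:
    def test_true_genotypes_recovered(self, small_run, small_bins):
        catalog, table, _ = call_genotypes(small_bins.assigned)
        pool_name = {s: n for n, s in small_run["pool"].sequences.items()}
        truth_sets = {g.individual_id: set(g.distinct_alleles)
                      for g in small_run["genotypes"]}
        exact = 0
        n_pass = 0
        for ind, row in table.pass_rows():
            n_pass += 1
            called = {pool_name.get(catalog.entries[a].sequence) for a, _ in row}
            # no allele outside the truth set may ever be called
            assert called <= truth_sets[ind]
            exact += called == truth_sets[ind]
        assert n_pass > 0
        assert exact / n_pass >= 0.9
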