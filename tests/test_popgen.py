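"""Polymorphism statistics against brute-force oracles and sign behaviour."""

import math
from itertools import combinations

import numpy as np
import pytest

from mhctyper import popgen
from mhctyper import simulate as sim
from mhctyper.calling import GenotypeTable


# ---------------------------------------------------------------- oracles
def oracle_s_eta(seqs):
    S = eta = 0
    for col in zip(*seqs):
        if set(col) - set("ACGT"):
            continue
        k = len(set(col))
        if k > 1:
            S += 1
            eta += k - 1
    return S, eta


def oracle_pi_k(seqs):
    keep = [i for i, col in enumerate(zip(*seqs)) if not set(col) - set("ACGT")]
    diffs = [
        sum(a[i] != b[i] for i in keep) for a, b in combinations(seqs, 2)
    ]
    k = sum(diffs) / len(diffs)
    return k / len(keep), k


def oracle_tajima(seqs):
    """Textbook formula, coded independently of the implementation."""
    n = len(seqs)
    S, _ = oracle_s_eta(seqs)
    if S == 0:
        return None
    _, k = oracle_pi_k(seqs)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def random_alignment(rng, n, L, p_var=0.3):
    base = rng.choice(list("ACGT"), size=L)
    seqs = []
    for _ in range(n):
        s = base.copy()
        mask = rng.random(L) < p_var
        for i in np.nonzero(mask)[0]:
            s[i] = rng.choice([b for b in "ACGT" if b != base[i]])
        seqs.append("".join(s))
    return seqs


class TestSegregatingSites:
    def test_identical_sequences(self):
        assert popgen.segregating_sites(["ACGT"] * 4) == (0, 0)

    def test_random_alignments_match_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            seqs = random_alignment(rng, int(rng.integers(2, 8)), 30)
            assert popgen.segregating_sites(seqs) == oracle_s_eta(seqs)

    def test_multiallelic_column_counts_extra_mutations(self):
        seqs = ["AAAA", "CAAA", "GAAA"]
        assert popgen.segregating_sites(seqs) == (1, 2)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            popgen.segregating_sites(["ACGT", "ACG"])


class TestDiversity:
    def test_two_sequences_three_diffs(self):
        a = "A" * 30
        b = "T" * 3 + "A" * 27
        pi, k = popgen.diversity([a, b])
        assert k == 3
        assert pi == pytest.approx(0.1)

    def test_random_alignments_match_bruteforce(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            seqs = random_alignment(rng, 5, 60)
            pi, k = popgen.diversity(seqs)
            opi, ok_ = oracle_pi_k(seqs)
            assert k == pytest.approx(ok_, abs=1e-12)
            assert pi == pytest.approx(opi, abs=1e-12)

    def test_pi_times_length_equals_k(self):
        rng = np.random.default_rng(29)
        seqs = random_alignment(rng, 6, 45)
        pi, k = popgen.diversity(seqs)
        assert pi * 45 == pytest.approx(k, abs=1e-12)

    def test_gap_columns_excluded(self):
        seqs = ["AC-T", "ACGT", "TCGT"]
        pi, k = popgen.diversity(seqs)  # column 3 dropped entirely
        S, eta = popgen.segregating_sites(seqs)
        assert (S, eta) == (1, 1)
        assert pi == pytest.approx(k / 3)


class TestTajimasD:
    def test_matches_independent_formula(self):
        rng = np.random.default_rng(31)
        checked = 0
        while checked < 40:
            seqs = random_alignment(rng, int(rng.integers(4, 10)), 40)
            expected = oracle_tajima(seqs)
            if expected is None:
                continue
            assert popgen.tajimas_d(seqs) == pytest.approx(expected, abs=1e-9)
            checked += 1

    def test_sign_reflects_frequency_spectrum(self):
        n, L = 10, 40
        base = ["A"] * L
        # every variant a singleton -> negative D
        singletons = []
        for i in range(n):
            s = base.copy()
            if i < 8:
                s[i] = "T"
            singletons.append("".join(s))
        # every variant at 50% -> positive D
        half = []
        for i in range(n):
            s = base.copy()
            if i < n // 2:
                for j in range(8):
                    s[j] = "T"
            half.append("".join(s))
        assert popgen.tajimas_d(singletons) < 0 < popgen.tajimas_d(half)

    def test_undefined_without_variation(self):
        assert popgen.tajimas_d(["ACGT"] * 5) is None

    def test_invariant_under_relabeling_and_complement(self):
        rng = np.random.default_rng(37)
        seqs = random_alignment(rng, 6, 50)
        d = popgen.tajimas_d(seqs)
        shuffled = list(reversed(seqs))
        comp = [s.translate(str.maketrans("ACGT", "TGCA")) for s in seqs]
        assert popgen.tajimas_d(shuffled) == pytest.approx(d, abs=1e-12)
        assert popgen.tajimas_d(comp) == pytest.approx(d, abs=1e-12)

    def test_neutral_pools_unbiased_balanced_pools_positive(self):
        """Coalescent pools give mean D near 0; deep-split pools emulate
        balancing selection and push D well above 1."""
        neutral, balanced = [], []
        for seed in range(60):
            pool = sim.generate_allele_pool(25, seed=seed, exon_len=150,
                                            intron_tail_len=0)
            d = popgen.tajimas_d([s for _, s in pool.alleles])
            if d is not None:
                neutral.append(d)
            pool_b = sim.generate_allele_pool(25, seed=seed, exon_len=150,
                                              intron_tail_len=0, deep_split=3.0)
            db = popgen.tajimas_d([s for _, s in pool_b.alleles])
            if db is not None:
                balanced.append(db)
        assert -0.5 <= np.mean(neutral) <= 0.5
        assert np.mean(balanced) > 1.0


class TestSlidingTajima:
    def test_constant_alignment_all_undefined(self):
        prof = popgen.sliding_tajima(["ACGTACGTACGTACGTACGTACGTACGT"] * 5)
        assert all(d is None for _, _, d in prof.windows)

    def test_full_window_reduces_to_global(self):
        rng = np.random.default_rng(41)
        seqs = random_alignment(rng, 5, 30)
        prof = popgen.sliding_tajima(seqs, window=30, step=7)
        assert len(prof.windows) == 1
        assert prof.windows[0][2] == pytest.approx(popgen.tajimas_d(seqs))

    def test_variation_restricted_to_first_window(self):
        L = 48
        a = "A" * L
        b = "T" * 10 + "A" * (L - 10)
        c = "T" * 5 + "A" * (L - 5)
        d = "G" * 7 + "A" * (L - 7)
        prof = popgen.sliding_tajima([a, b, c, d], window=24, step=24)
        assert prof.windows[0][2] is not None
        assert prof.windows[1][2] is None

    def test_window_coordinates(self):
        seqs = ["ACGT" * 12] * 4
        prof = popgen.sliding_tajima(seqs, window=24, step=3)
        assert prof.windows[0][:2] == (1, 24)
        assert prof.windows[1][:2] == (4, 27)
        assert prof.windows[-1][1] <= 48

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            popgen.sliding_tajima(["ACGTACGT"] * 4, window=3)


class TestProteinCollapse:
    def test_synonymous_pair_collapses(self):
        # GGT and GGC both encode Gly
        seqs = {"a1": "GGTAAA", "a2": "GGCAAA"}
        classes, stops = popgen.collapse_to_protein(seqs, counts={"a1": 5, "a2": 2},
                                                    intron_tail_len=0)
        assert classes == {"a1": ["a1", "a2"]}
        assert stops == []

    def test_class_named_after_most_common_member(self):
        seqs = {"a1": "GGTAAA", "a2": "GGCAAA"}
        classes, _ = popgen.collapse_to_protein(seqs, counts={"a1": 1, "a2": 9},
                                                intron_tail_len=0)
        assert list(classes) == ["a2"]

    def test_stop_codon_excluded(self):
        seqs = {"ok": "GGTAAA", "bad": "TAAAAA"}
        classes, stops = popgen.collapse_to_protein(seqs, intron_tail_len=0)
        assert stops == ["bad"]
        assert "bad" not in {m for v in classes.values() for m in v}

    def test_intron_trim_and_frame(self):
        pool = sim.generate_allele_pool(10, seed=51)
        classes, stops = popgen.collapse_to_protein(pool.sequences)
        assert stops == []
        assert sum(len(v) for v in classes.values()) == 10

    def test_bad_frame_rejected(self):
        with pytest.raises(ValueError):
            popgen.collapse_to_protein({"x": "GGTAA"}, intron_tail_len=0)


def _table(rows, totals=None):
    return GenotypeTable(
        rows=rows,
        total_reads_map=totals or {k: sum(d for _, d in v) for k, v in rows.items()},
    )


class TestSpectrumAndCorrelation:
    def test_shared_allele_counted_once_per_individual(self):
        t = _table({"b1": [("x", 40)], "b2": [("x", 10), ("y", 5)]})
        spec = popgen.allele_spectrum(t)
        assert spec["x"] == 2
        assert spec["y"] == 1

    def test_empty_table(self):
        spec = popgen.allele_spectrum(_table({}))
        assert spec.empty

    def test_spectrum_matches_truth_tally(self, small_run, small_bins):
        from mhctyper.calling import call_genotypes

        catalog, table, _ = call_genotypes(small_bins.assigned)
        spec = popgen.allele_spectrum(table)
        pool_name = {s: n for n, s in small_run["pool"].sequences.items()}
        truth_tally = {}
        passing = {ind for ind, _ in table.pass_rows()}
        for g in small_run["genotypes"]:
            if g.individual_id in passing:
                for a in g.distinct_alleles:
                    truth_tally[a] = truth_tally.get(a, 0) + 1
        for allele, count in spec.items():
            true_name = pool_name[catalog.entries[allele].sequence]
            assert count <= truth_tally[true_name]

    def test_perfect_proportionality(self):
        rows = {f"b{i}": [(f"a{j}", 10) for j in range(i)] for i in range(1, 6)}
        t = _table(rows, totals={f"b{i}": 100 * i for i in range(1, 6)})
        r, p = popgen.reads_vs_alleles_correlation(t)
        assert r == pytest.approx(1.0)

    def test_matches_closed_form_pearson(self):
        rows = {
            "b1": [("a", 5)], "b2": [("a", 5), ("b", 5)],
            "b3": [("a", 5)], "b4": [("a", 5), ("b", 5), ("c", 5)],
        }
        totals = {"b1": 30, "b2": 100, "b3": 50, "b4": 80}
        r, p = popgen.reads_vs_alleles_correlation(_table(rows, totals))
        x = np.array([30, 100, 50, 80], dtype=float)
        y = np.array([1, 2, 1, 3], dtype=float)
        rx = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(rx, abs=1e-12)

    def test_zero_variance_signalled(self):
        rows = {f"b{i}": [("a", 10)] for i in range(5)}
        with pytest.raises(ValueError):
            popgen.reads_vs_alleles_correlation(_table(rows))
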