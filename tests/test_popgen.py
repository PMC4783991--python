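import itertools
import math

import numpy as np
import pytest

from allelescan.gene_model import GeneModel
from allelescan.popgen import (
    AlignmentInputError,
    MultipleAlignment,
    diversity_report,
    five_partition_report,
    haplotype_diversity,
    harmonic,
    nucleotide_diversity,
    partition_alignment,
    segregating_and_indel_sites,
    subset_rows,
    watterson_theta,
)
from allelescan.simulate import SimConfig, simulate_alleles


# ---------------------------------------------------------------- oracles

def brute_complete_columns(rows):
    return [i for i in range(len(rows[0]))
            if all(r[i] not in "-N" for r in rows)]


def brute_pi(rows):
    cols = brute_complete_columns(rows)
    if not cols:
        return None
    diffs = [sum(a[i] != b[i] for i in cols)
             for a, b in itertools.combinations(rows, 2)]
    return sum(diffs) / len(diffs) / len(cols)


def brute_hd(rows):
    cols = brute_complete_columns(rows)
    if not cols:
        return None
    haps = ["".join(r[i] for i in cols) for r in rows]
    n = len(rows)
    sum2 = sum((haps.count(h) / n) ** 2 for h in set(haps))
    return n * (1 - sum2) / (n - 1)


def brute_theta_w(rows):
    cols = brute_complete_columns(rows)
    if not cols:
        return None
    S = sum(1 for i in cols if len({r[i] for r in rows}) > 1)
    a_n = sum(1.0 / k for k in range(1, len(rows)))
    return S / (a_n * len(cols))


def random_alignment(rng, n, L, gap_p=0.05, n_p=0.02):
    base = rng.choice(list("ACGT"), size=L)
    rows = []
    for _ in range(n):
        row = base.copy()
        mut = rng.random(L) < 0.08
        row[mut] = rng.choice(list("ACGT"), size=int(mut.sum()))
        gaps = rng.random(L) < gap_p
        row[gaps] = "-"
        ns = rng.random(L) < n_p
        row[ns] = "N"
        rows.append("".join(row))
    return MultipleAlignment(
        ids=tuple(f"s{i}" for i in range(n)), rows=tuple(rows))


# ----------------------------------------------------------------- tests

class TestSiteCounts:
    def test_identical_rows(self):
        aln = MultipleAlignment(("a", "b"), ("ACGT", "ACGT"))
        assert segregating_and_indel_sites(aln) == (0, 0, 4)

    def test_single_snp(self):
        aln = MultipleAlignment(("a", "b"), ("ACGT", "ACCT"))
        assert segregating_and_indel_sites(aln)[0] == 1

    def test_hand_counted_mixed_columns(self):
        aln = MultipleAlignment(("a", "b", "c"), ("AC-T", "ACGT", "ACGA"))
        S, indels, L = segregating_and_indel_sites(aln)
        assert (S, indels, L) == (1, 1, 3)

    def test_single_row_rejected(self):
        with pytest.raises(AlignmentInputError):
            MultipleAlignment(("a",), ("ACGT",))


class TestHaplotypeDiversity:
    def test_monomorphic_is_zero(self):
        aln = MultipleAlignment(("a", "b", "c"), ("ACGT",) * 3)
        assert haplotype_diversity(aln)[0] == 0.0

    def test_two_distinct_rows_give_unity(self):
        aln = MultipleAlignment(("a", "b"), ("ACGT", "ACCT"))
        assert haplotype_diversity(aln)[0] == pytest.approx(1.0)

    def test_published_haplotype_class_sizes_give_0973(self):
        # 29 alleles in classes {4, 3, 2, 2, 18 singletons} -> Hd = 0.973
        sizes = [4, 3, 2, 2] + [1] * 18
        rows, ids = [], []
        for h, size in enumerate(sizes):
            for rep in range(size):
                ids.append(f"h{h}_{rep}")
                rows.append(format(h, "05b").replace("0", "A").replace("1", "C"))
        aln = MultipleAlignment(tuple(ids), tuple(rows))
        hd, sd, n_hap = haplotype_diversity(aln)
        assert n_hap == 22
        assert round(hd, 3) == 0.973

    def test_duplicating_a_row_never_increases_hd(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            aln = random_alignment(rng, 5, 40)
            hd0 = haplotype_diversity(aln)[0]
            dup = MultipleAlignment(aln.ids + ("dup",), aln.rows + (aln.rows[0],))
            assert haplotype_diversity(dup)[0] <= hd0 + 1e-12


class TestAgainstBruteForce:
    @pytest.mark.parametrize("seed", range(8))
    def test_pi_hd_theta_match_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        L = int(rng.integers(10, 301))
        aln = random_alignment(rng, n, L)
        pi, _ = nucleotide_diversity(aln)
        hd, _, _ = haplotype_diversity(aln)
        tw, _ = watterson_theta(aln)
        for got, want in ((pi, brute_pi(aln.rows)),
                          (hd, brute_hd(aln.rows)),
                          (tw, brute_theta_w(aln.rows))):
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        aln = random_alignment(rng, 6, 60)
        perm_rows = tuple(aln.rows[i] for i in rng.permutation(6))
        shuffled = MultipleAlignment(aln.ids, perm_rows)
        assert haplotype_diversity(shuffled)[0] == pytest.approx(haplotype_diversity(aln)[0])
        cols = rng.permutation(60)
        col_rows = tuple("".join(r[c] for c in cols) for r in aln.rows)
        col_shuffled = MultipleAlignment(aln.ids, col_rows)
        assert nucleotide_diversity(col_shuffled)[0] == pytest.approx(
            nucleotide_diversity(aln)[0])
        assert watterson_theta(col_shuffled)[0] == pytest.approx(watterson_theta(aln)[0])


class TestWattersonArithmetic:
    def test_two_sequences(self):
        aln = MultipleAlignment(("a", "b"), ("A" * 99 + "C", "A" * 99 + "T"))
        tw, _ = watterson_theta(aln)
        assert tw == pytest.approx(0.01)

    def test_four_sequences_harmonic_sum(self):
        # S = 5 over L = 100 with n = 4: a_n = 1 + 1/2 + 1/3
        rows = ["A" * 100 for _ in range(4)]
        base = list(rows[1])
        for i in range(5):
            base[i] = "C"
        rows[1] = "".join(base)
        aln = MultipleAlignment(("a", "b", "c", "d"), tuple(rows))
        tw, _ = watterson_theta(aln)
        assert tw == pytest.approx(5 / ((1 + 0.5 + 1 / 3) * 100))
        assert harmonic(4) == pytest.approx(1 + 0.5 + 1 / 3)

    def test_no_segregating_sites_gives_zero_with_zero_sd(self):
        aln = MultipleAlignment(("a", "b"), ("ACGT", "ACGT"))
        assert watterson_theta(aln) == (0.0, 0.0)


class TestPartition:
    def test_single_exon_model_puts_everything_in_exons(self):
        aln = MultipleAlignment(("r", "b"), ("ACGTACGT", "ACGTACGA"))
        model = GeneModel.from_exons([(1, 8)])
        parts = partition_alignment(aln, model, "r")
        assert parts["exons"].length == 8 and parts["introns"] is None

    def test_column_counts_partition_total(self, gene_model, reference):
        cfg = SimConfig(seed=7, snp_rate=0.01, n_alleles=4)
        records, _ = simulate_alleles(reference, gene_model, cfg)
        rows = tuple(r.seq for r in records) + (reference.seq,)
        ids = tuple(r.id for r in records) + ("reference",)
        aln = MultipleAlignment(ids, rows)  # no indels planted -> already aligned
        parts = partition_alignment(aln, gene_model, "reference")
        assert parts["exons"].length == gene_model.cds_length()
        assert parts["exons"].length + parts["introns"].length == aln.length

    def test_missing_reference_row_is_error(self):
        aln = MultipleAlignment(("a", "b"), ("ACGT", "ACGT"))
        with pytest.raises(AlignmentInputError):
            partition_alignment(aln, GeneModel.from_exons([(1, 4)]), "zz")


class TestSubsetRows:
    def test_partition_by_functionality(self):
        aln = MultipleAlignment(tuple("abcd"), ("ACGT",) * 4)
        calls = {"a": "functional", "b": "disabled", "c": "disabled", "d": "disabled"}
        sub = subset_rows(aln, calls, "disabled")
        assert sub.ids == ("b", "c", "d")

    def test_single_member_partition_warns_and_skips(self):
        aln = MultipleAlignment(tuple("abc"), ("ACGT",) * 3)
        calls = {"a": "functional", "b": "disabled", "c": "disabled"}
        with pytest.warns(UserWarning, match="functional"):
            assert subset_rows(aln, calls, "functional") is None


class TestDiversityReport:
    def test_identical_rows_report_zero_diversity(self):
        aln = MultipleAlignment(("a", "b"), ("ACGTACGT", "ACGTACGT"))
        rep = diversity_report(aln, "test")
        assert (rep.Hd, rep.pi, rep.theta_w) == (0.0, 0.0, 0.0)
        assert rep.pct_identity == pytest.approx(100.0)

    def test_densities_divide_by_total_length(self):
        aln = MultipleAlignment(("a", "b"), ("AC-TACGT", "ACGTACGA"))
        rep = diversity_report(aln, "test")
        assert rep.snp_per_kb == pytest.approx(1000 * rep.S / 8)
        assert rep.indel_per_kb == pytest.approx(1000 * 1 / 8)

    def test_five_partition_layout(self, gene_model, reference):
        cfg = SimConfig(seed=13, snp_rate=0.008, n_alleles=6)
        records, truth = simulate_alleles(reference, gene_model, cfg)
        rows = tuple(r.seq for r in records) + (reference.seq,)
        ids = tuple(r.id for r in records) + ("reference",)
        aln = MultipleAlignment(ids, rows)
        calls = dict(truth.status_of())
        calls["reference"] = "functional"
        calls[ids[0]] = calls[ids[1]] = "disabled"  # force a two-member partition
        table = five_partition_report(aln, gene_model, "reference", calls)
        assert list(table["partition_label"]) == [
            "genomic", "exons", "introns", "functional", "nonfunctional"]

    def test_pi_matches_mutation_rate_expectation(self, gene_model):
        # Star genealogy: two alleles differ at a site if exactly one mutated,
        # or both mutated to different bases. SNPs avoid the 48 border bases
        # and the 6 start/stop bases, which never vary.
        mu = 0.0075
        pis = []
        for seed in range(20):
            cfg = SimConfig(seed=100 + seed, snp_rate=mu, n_alleles=10)
            reference, model, records, _ = __import__(
                "allelescan.simulate", fromlist=["simulate_dataset"]
            ).simulate_dataset(cfg)
            aln = MultipleAlignment(
                tuple(r.id for r in records), tuple(r.seq for r in records))
            pis.append(nucleotide_diversity(aln)[0])
        L = gene_model.span[1]
        eligible = (L - 48 - 6) / L
        expected = (2 * mu * (1 - mu) + mu * mu * 2 / 3) * eligible
        se = np.std(pis, ddof=1) / math.sqrt(len(pis))
        assert abs(np.mean(pis) - expected) <= 3 * se
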