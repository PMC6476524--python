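"""Read processing: orientation/merging, clustering, error rates, frequencies."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fitscape.reads import (
    FrequencyTable,
    InsertionRecord,
    ReadCountTable,
    cluster_correct,
    compute_frequencies,
    estimate_error_rates,
    expected_miscalled_variant_frequency,
    expected_real_variant_frequency,
    merge_amino_acid,
    miscalled_read_fraction,
    orient_and_merge,
    revcomp,
    template_switch_free_fraction,
)

CR = "GGTTCTGGT"


def make_pair(amplicon, quality=30, read_len=None):
    """Paired reads covering the whole amplicon (forward + reverse-complement)."""
    read_len = read_len or len(amplicon)
    fwd = amplicon[:read_len]
    rev = revcomp(amplicon)[:read_len]
    return (fwd, [quality] * len(fwd)), (rev, [quality] * len(rev))


class TestOrientAndMerge:
    amplicon = "ACGTAAAC" + CR + "TTGCACGG"

    def test_identical_overlapping_mates_give_the_amplicon(self):
        merged, stats = orient_and_merge([make_pair(self.amplicon)], CR)
        assert merged == [self.amplicon]
        assert stats["merged"] == 1

    def test_swapped_mates_are_reoriented(self):
        p1, p2 = make_pair(self.amplicon)
        merged, _ = orient_and_merge([(p2, p1)], CR)
        assert merged == [self.amplicon]

    def test_overlap_mismatch_resolved_by_higher_quality_base(self):
        (fwd, qf), (rev, qr) = make_pair(self.amplicon)
        # plant a disagreement at position 2: forward says G, reverse says T
        fwd = fwd[:2] + "G" + fwd[3:]
        pos_in_rev = len(self.amplicon) - 1 - 2
        rev = rev[:pos_in_rev] + "A" + rev[pos_in_rev + 1 :]  # A -> revcomp T
        qf, qr = list(qf), list(qr)
        qf[2] = 10
        qr[pos_in_rev] = 35  # reverse base wins
        merged, _ = orient_and_merge([((fwd, qf), (rev, qr))], CR)
        assert merged[0][2] == "T"
        # forward wins on ties and on higher forward quality
        qf[2] = 35
        qr[pos_in_rev] = 35
        merged, _ = orient_and_merge([((fwd, qf), (rev, qr))], CR)
        assert merged[0][2] == "G"

    def test_reads_without_constant_region_are_discarded_and_counted(self):
        junk = ("ACGTACGTACGTACGTACGTACGT", [30] * 24)
        merged, stats = orient_and_merge([(junk, junk)], CR)
        assert merged == []
        assert stats["no_constant"] == 1

    def test_remaining_n_discards_read(self):
        amplicon = self.amplicon.replace("ACGG", "NCGG")
        merged, stats = orient_and_merge([make_pair(amplicon)], CR)
        assert merged == []
        assert stats["ambiguous_n"] == 1

    def test_primers_are_trimmed(self):
        left, right = "CCAATT", "GGCCAA"
        amplicon = left + self.amplicon + right
        merged, _ = orient_and_merge([make_pair(amplicon)], CR, primers=(left, right))
        assert merged == [self.amplicon]


class TestClusterCorrect:
    def test_singletons_merge_into_dominant_parent(self):
        parent = "ACGTACGTACGTACGTACGT"
        counts = {parent: 10_000}
        # 30 singletons at edit distance 1 (brute-force nearest neighbour is
        # trivially the single dominant parent)
        muts = []
        for i in range(20):
            for b in "CGT":
                if b != parent[i]:
                    muts.append(parent[:i] + b + parent[i + 1 :])
        for m in muts[:30]:
            counts[m] = 1
        corrected = cluster_correct(counts)
        assert corrected == {parent: 10_030}

    def test_equal_count_sequences_both_retained(self):
        a = "ACGTACGT"
        b = "ACGTATTT"  # distance 2, but no dominant parent
        counts = {a: 50, b: 50}
        corrected = cluster_correct(counts)
        assert corrected == counts

    def test_sequence_beyond_radius_retained(self):
        a = "AAAAAAAAAA"
        b = "AAATTTAAAA"  # distance 3
        corrected = cluster_correct({a: 1000, b: 1})
        assert corrected == {a: 1000, b: 1}

    @pytest.mark.parametrize("seed", [0, 1])
    def test_total_count_conserved(self, seed):
        rng = np.random.default_rng(seed)
        seqs = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(60)]
        counts = {s: int(rng.integers(1, 2000)) for s in set(seqs)}
        corrected = cluster_correct(counts)
        assert sum(corrected.values()) == sum(counts.values())


class TestErrorRates:
    def test_error_free_reads_give_zero_rates(self):
        amplicon = "ACGTAAAC" + CR + "TTGCACGG"
        pairs = [make_pair(amplicon) for _ in range(10)]
        lo = amplicon.index(CR)
        rates = estimate_error_rates(
            read_pairs=pairs,
            variant_counts={amplicon: 1000},
            constant_region_span=(lo, lo + len(CR)),
        )
        assert rates.raw_per_nt == 0.0
        assert rates.calling_per_nt == 0.0

    def test_raw_rate_counts_overlap_mismatches(self):
        amplicon = "ACGTAAAC" + CR + "TTGCACGG"
        (fwd, qf), (rev, qr) = make_pair(amplicon)
        rev = "T" + rev[1:]  # one mismatch in the overlap
        rates = estimate_error_rates(read_pairs=[((fwd, qf), (rev, qr))])
        assert rates.raw_per_nt == pytest.approx(1 / len(amplicon))

    def test_expected_variant_frequencies_match_in_library_arithmetic(self):
        # 0.04% per-nt error over a 60-nt amplicon: 2.4% of reads miscalled
        frac = miscalled_read_fraction(0.0004, 60)
        assert frac == pytest.approx(0.024)
        miscalled = expected_miscalled_variant_frequency(frac, 31_815_448)
        real = expected_real_variant_frequency(1 - frac, 176_879)
        assert miscalled == pytest.approx(8e-10, abs=0.5e-10)
        assert real == pytest.approx(6e-6, abs=0.5e-6)

    def test_planted_constant_region_error_rate_recovered(self, rng):
        # reads from 50 variants; errors injected in the constant region at a
        # known per-nt rate
        rate = 2e-3
        variants = []
        for _ in range(50):
            var = "".join(rng.choice(list("ACGT"), 8))
            variants.append(var + CR + "".join(rng.choice(list("ACGT"), 8)))
        lo, hi = 8, 8 + len(CR)
        counts: dict[str, int] = {}
        per_variant = 20_000
        for seq in variants:
            n_err = rng.binomial(per_variant, rate * len(CR))
            counts[seq] = counts.get(seq, 0) + per_variant - n_err
            for _ in range(n_err):
                pos = lo + rng.integers(len(CR))
                alt = rng.choice([b for b in "ACGT" if b != seq[pos]])
                mut = seq[:pos] + alt + seq[pos + 1 :]
                counts[mut] = counts.get(mut, 0) + 1
        rates = estimate_error_rates(
            variant_counts=counts, constant_region_span=(lo, hi)
        )
        assert rates.calling_per_nt == pytest.approx(rate, rel=0.10)


class TestTemplateSwitching:
    def test_in_library_counts_imply_more_than_98_6_percent_free(self):
        # 11,454 insertion-bearing variants of which 76 share an insertion
        # unique insertion signatures: never flagged
        records = [
            InsertionRecord(f"v{i}", "L", i, "AAC", f"R{i}")
            for i in range(11_454 - 76)
        ]
        for p in range(38):  # 38 sharing pairs -> 76 flagged variants
            for member in range(2):
                records.append(
                    InsertionRecord(f"s{p}_{member}", "R", p, "TTGG", f"R{p}_{member}")
                )
        est = template_switch_free_fraction(records)
        assert est.n_variants == 11_454
        assert est.n_flagged == 76
        assert est.percent_free >= 98.6

    def test_no_shared_insertions_is_fully_free(self):
        records = [InsertionRecord("a", "L", 3, "AAT", "X"),
                   InsertionRecord("b", "R", 5, "GGC", "Y")]
        assert template_switch_free_fraction(records).percent_free == 100.0

    def test_empty_input_signalled(self):
        with pytest.raises(ValueError):
            template_switch_free_fraction([])

    def test_planted_switch_rate_recovered(self, rng):
        # each variant carries a unique left-half insertion; switching
        # replaces the right half with another variant's
        n = 4000
        rate = 0.05
        records = []
        n_switched = 0
        for i in range(n):
            records.append(InsertionRecord(f"v{i}", "L", i, f"AA{i % 7}", f"R{i}"))
            if rng.random() < rate:
                n_switched += 1
                records.append(
                    InsertionRecord(f"v{i}x", "L", i, f"AA{i % 7}", f"R{(i+1) % n}")
                )
        est = template_switch_free_fraction(records)
        # both members of each sharing pair are flagged
        implicated = est.n_flagged / est.n_variants
        expected = 2 * n_switched / (n + n_switched)
        se = np.sqrt(rate * (1 - rate) / n) * 2
        assert implicated == pytest.approx(expected, abs=2 * se)


def make_rct(count_map):
    tables = {}
    for (rep, t), counts in count_map.items():
        tables[(rep, t)] = counts
    return ReadCountTable.from_dicts(tables)


class TestComputeFrequencies:
    def test_consensus_mean_when_replicates_agree(self):
        depth = 100_000
        counts = {
            (r, t): {"AAA": 1, "CCC": depth - 1} for r in (1, 2, 3, 4) for t in (0, 1, 2)
        }
        ft = compute_frequencies(make_rct(counts), min_reads_per_replicate=1)
        assert ft.consensus.loc["AAA", 0] == pytest.approx(1 / depth)

    def test_outlier_replicate_triggers_median(self):
        depth = 100_000
        counts = {}
        for r in (1, 2, 3, 4):
            for t in (0, 1, 2):
                n = 90 if (r == 4 and t == 0) else 1  # rep 4 is an outlier at t0
                counts[(r, t)] = {"AAA": n, "CCC": depth - n}
        ft = compute_frequencies(make_rct(counts), min_reads_per_replicate=1)
        f = np.array([1e-5, 1e-5, 1e-5, 90e-5])
        assert abs(f.mean() - np.median(f)) > np.median(f)  # rule fires
        assert ft.consensus.loc["AAA", 0] == pytest.approx(1e-5)

    def test_genotype_below_ten_reads_in_one_replicate_excluded(self):
        depth = 10_000
        counts = {}
        for r in (1, 2, 3, 4):
            for t in (0, 1, 2):
                # replicate 3 sums to only 9 reads across the time points
                n = 3 if r == 3 else 10
                counts[(r, t)] = {"AAA": n, "CCC": depth - n}
        rct = make_rct(counts)
        assert rct.counts.loc["AAA"].groupby(level="rep").sum()[3] == 9
        ft = compute_frequencies(rct)
        assert "AAA" not in ft.consensus.index
        assert "CCC" in ft.consensus.index

    def test_missing_replicate_rejected(self):
        counts = {(r, t): {"AAA": 10} for r in (1, 2, 3) for t in (0, 1, 2)}
        with pytest.raises(ValueError, match="4 replicates"):
            compute_frequencies(make_rct(counts))

    def test_frequencies_sum_below_one_when_reads_filtered(self, rng):
        depth = 1000
        counts = {}
        for r in (1, 2, 3, 4):
            for t in (0, 1, 2):
                counts[(r, t)] = {"AAA": 500, "CCC": 495, "TTT": 5}
        ft = compute_frequencies(make_rct(counts), min_reads_per_replicate=100)
        total = ft.consensus[0].sum()
        assert total < 1.0


class TestMergeAminoAcid:
    def _ft(self, consensus, variance=None):
        idx = list(consensus)
        cons = pd.DataFrame(
            {t: [consensus[g][t] for g in idx] for t in (0, 1, 2)}, index=idx
        )
        var = pd.DataFrame(1e-12, index=idx, columns=[0, 1, 2])
        reps = pd.DataFrame(
            np.tile(cons.to_numpy(), 4),
            index=idx,
            columns=pd.MultiIndex.from_tuples(
                [(r, t) for r in (1, 2, 3, 4) for t in (0, 1, 2)], names=["rep", "t"]
            ),
        )
        return FrequencyTable(rep_freqs=reps, consensus=cons, depths=None, level="nt",
                              variance=var)

    def test_synonymous_frequencies_and_variances_sum(self):
        ft = self._ft({"AAA": (2e-6, 1e-6, 0.5e-6), "AAG": (1e-6, 0.5e-6, 0.25e-6)})
        ft.variance = pd.DataFrame(
            [[1e-12, 2e-12, 3e-12], [1e-12, 1e-12, 1e-12]],
            index=["AAA", "AAG"], columns=[0, 1, 2],
        )
        merged = merge_amino_acid(ft, {"AAA": "K", "AAG": "K"})
        assert merged.consensus.loc["K"].tolist() == pytest.approx(
            [3e-6, 1.5e-6, 0.75e-6]
        )
        assert merged.variance.loc["K"].tolist() == pytest.approx([2e-12, 3e-12, 4e-12])
        assert merged.n_synonyms["K"] == 2

    @pytest.mark.parametrize(
        "trajectory,kept",
        [
            ((0.0, 0.0, 5e-6), False),
            ((0.0, 5e-6, 0.0), False),
            ((5e-6, 0.0, 5e-6), False),
            ((5e-6, 2e-6, 0.0), True),   # dropout: handled later as boundary
            ((5e-6, 2e-6, 1e-6), True),
        ],
    )
    def test_implausible_trajectories_filtered(self, trajectory, kept):
        ft = self._ft({"AAA": trajectory})
        merged = merge_amino_acid(ft, {"AAA": "K"})
        assert ("K" in merged.consensus.index) == kept
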