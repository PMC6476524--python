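"""Read processing: from raw paired reads or count tables to frequency tables.

Covers orientation/merging of unoriented read pairs around the constant
region, greedy error-correction clustering, sequencing-error and
template-switching rate estimation, replicate frequency computation with the
outlier-robust mean/median consensus rule, and merging of synonymous
nucleotide genotypes into amino-acid genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import edlib
import numpy as np
import pandas as pd

REPLICATES = (1, 2, 3, 4)
TIMEPOINTS = (0, 1, 2)

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# count and frequency containers
# ---------------------------------------------------------------------------

class ReadCountTable:
    """Integer read counts per nucleotide genotype x replicate x time point.

    ``counts`` is a DataFrame indexed by genotype with MultiIndex columns
    (replicate 1-4, timepoint 0-2).  Column sums are the sequencing depths
    N_i^t used throughout the noise model and boundary-fitness formula.
    """

    def __init__(self, counts: pd.DataFrame):
        counts = counts.fillna(0).astype(np.int64)
        counts.columns = pd.MultiIndex.from_tuples(
            [(int(r), int(t)) for r, t in counts.columns], names=["rep", "t"]
        )
        if (counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        self.counts = counts.sort_index(axis=1)

    @classmethod
    def from_dicts(cls, tables: Mapping[tuple[int, int], Mapping[str, int]]) -> "ReadCountTable":
        df = pd.DataFrame(
            {key: pd.Series(tab, dtype=np.int64) for key, tab in tables.items()}
        )
        return cls(df)

    @property
    def depths(self) -> pd.Series:
        """Total reads per (replicate, timepoint)."""
        return self.counts.sum(axis=0)

    def frequencies(self) -> pd.DataFrame:
        return self.counts / self.depths

    def to_tsv(self, path) -> None:
        long = (
            self.counts.stack(["rep", "t"], future_stack=True)
            .rename("count")
            .reset_index()
            .rename(columns={"level_0": "genotype_nt"})
        )
        long = long[long["count"] > 0]
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReadCountTable":
        long = pd.read_csv(path, sep="\t")
        wide = long.pivot_table(
            index="genotype_nt", columns=["rep", "t"], values="count",
            aggfunc="sum", fill_value=0,
        )
        return cls(wide)


@dataclass
class FrequencyTable:
    """Per-genotype replicate frequencies, consensus frequency and variance.

    ``rep_freqs`` has MultiIndex columns (rep, t); ``consensus`` and
    ``variance`` have one column per timepoint.  ``level`` is "nt" or "aa".
    """

    rep_freqs: pd.DataFrame
    consensus: pd.DataFrame
    depths: pd.Series
    level: str = "nt"
    variance: pd.DataFrame | None = None
    n_synonyms: pd.Series | None = None

    @property
    def genotypes(self) -> pd.Index:
        return self.consensus.index

    def attach_variance(self, noise_model) -> None:
        """Assign sigma^2(f) per genotype and timepoint from a noise model."""
        var = {}
        for t in self.consensus.columns:
            var[t] = noise_model.variance(self.consensus[t].to_numpy(), t)
        self.variance = pd.DataFrame(var, index=self.consensus.index)


# ---------------------------------------------------------------------------
# read pair orientation and merging
# ---------------------------------------------------------------------------

def _locate(query: str, target: str, max_error_frac: float):
    k = int(math.floor(max_error_frac * len(query)))
    res = edlib.align(query, target, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    return start, end + 1


def orient_and_merge(
    read_pairs: Iterable[tuple[tuple[str, Iterable[int]], tuple[str, Iterable[int]]]],
    constant_region: str,
    primers: tuple[str, str] | None = None,
    max_error_frac: float = 0.2,
) -> tuple[list[str], dict[str, int]]:
    """Orient, merge and trim paired reads around the constant region.

    Each pair is ((seq, quality), (seq, quality)).  Reads are unoriented:
    the constant region is searched (inexact matching, up to
    ``max_error_frac`` errors) on both mates and the mates are swapped when
    the match lies on the second one.  The reverse mate is
    reverse-complemented and stitched to the forward mate at the offset
    implied by the two constant-region matches; in the overlap the
    higher-quality base wins (ties go to the forward mate).  Reads with a
    remaining 'N', or without a constant-region match on either mate, are
    discarded and counted.  Optional primers are trimmed so all merged
    sequences share coordinates.
    """
    merged: list[str] = []
    stats = {"merged": 0, "no_constant": 0, "no_anchor": 0, "ambiguous_n": 0,
             "no_primer": 0}
    for (seq1, qual1), (seq2, qual2) in read_pairs:
        seq1, seq2 = seq1.upper(), seq2.upper()
        qual1, qual2 = list(qual1), list(qual2)
        if _locate(constant_region, seq1, max_error_frac) is None:
            if _locate(constant_region, seq2, max_error_frac) is not None:
                seq1, seq2 = seq2, seq1
                qual1, qual2 = qual2, qual1
            else:
                stats["no_constant"] += 1
                continue
        r2 = revcomp(seq2)
        q2 = qual2[::-1]
        loc1 = _locate(constant_region, seq1, max_error_frac)
        loc2 = _locate(constant_region, r2, max_error_frac)
        if loc2 is None:
            stats["no_anchor"] += 1
            continue
        offset = loc1[0] - loc2[0]  # position of r2[0] in seq1 coordinates
        length = max(len(seq1), offset + len(r2))
        bases, quals = [], []
        for i in range(length):
            b1 = seq1[i] if i < len(seq1) else None
            j = i - offset
            b2 = r2[j] if 0 <= j < len(r2) else None
            if b1 is not None and b2 is not None:
                # consensus: higher-quality base, tie -> forward mate
                if qual1[i] >= q2[j]:
                    bases.append(b1)
                    quals.append(qual1[i])
                else:
                    bases.append(b2)
                    quals.append(q2[j])
            elif b1 is not None:
                bases.append(b1)
                quals.append(qual1[i])
            elif b2 is not None:
                bases.append(b2)
                quals.append(q2[j])
        consensus = "".join(bases)
        if "N" in consensus:
            stats["ambiguous_n"] += 1
            continue
        if primers is not None:
            left, right = primers
            locl = _locate(left, consensus, max_error_frac)
            locr = _locate(right, consensus, max_error_frac)
            if locl is None or locr is None:
                stats["no_primer"] += 1
                continue
            consensus = consensus[locl[1]: locr[0]]
        merged.append(consensus)
        stats["merged"] += 1
    return merged, stats


# ---------------------------------------------------------------------------
# error-correction clustering (abundance-greedy, starcode-like)
# ---------------------------------------------------------------------------

def cluster_correct(
    counts: Mapping[str, int], max_dist: int = 2, min_ratio: float = 5.0
) -> dict[str, int]:
    """Merge low-abundance sequences into nearby abundant ones.

    Sequences are visited in decreasing abundance; each sequence within edit
    distance ``max_dist`` of an already-accepted centroid at least
    ``min_ratio`` times more abundant is absorbed into the most abundant such
    centroid.  Total read count is conserved.  This is a simplified
    abundance-greedy scheme; ties (no sufficiently dominant parent) leave
    sequences unmerged.
    """
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    centroids: list[tuple[str, int]] = []  # (seq, original count), order = abundance
    corrected: dict[str, int] = {}
    for seq, cnt in items:
        if cnt <= 0:
            continue
        parent = None
        for cseq, ccnt in centroids:
            if ccnt < min_ratio * cnt:
                break  # centroids sorted by decreasing original count
            res = edlib.align(seq, cseq, mode="NW", task="distance", k=max_dist)
            if 0 <= res["editDistance"] <= max_dist:
                parent = cseq
                break
        if parent is None:
            centroids.append((seq, cnt))
            corrected[seq] = corrected.get(seq, 0) + cnt
        else:
            corrected[parent] += cnt
    return corrected


# ---------------------------------------------------------------------------
# sequencing-error and template-switching rates
# ---------------------------------------------------------------------------

@dataclass
class ErrorRates:
    raw_per_nt: float
    calling_per_nt: float
    miscalled_variant_frequency: float | None = None
    real_variant_frequency: float | None = None


def estimate_error_rates(
    read_pairs=None,
    variant_counts: Mapping[str, int] | None = None,
    constant_region_span: tuple[int, int] | None = None,
    n_possible_single_mutants: int | None = None,
    n_library_variants: int | None = None,
    read_length: int | None = None,
) -> ErrorRates:
    """Estimate per-nucleotide sequencing error rates.

    The *raw* rate is the mismatch fraction within the overlap of oriented
    mate pairs (each mismatch is an error on at least one mate).  The
    *variant-calling* rate is estimated from reads that differ from an
    abundant variant by exactly one nucleotide inside the constant region:
    since the variable regions are identical, such reads must be miscalls.
    When the library size and the number of possible single mutants are
    supplied, the expected frequencies of a specific miscalled variant
    (miscalled-read fraction / number of possible single mutants) and of a
    real variant (correct-read fraction / number of library variants) are
    also reported.
    """
    raw = math.nan
    if read_pairs is not None:
        mismatches = 0
        overlap_bases = 0
        # caller passes pre-oriented, co-extensive pairs (the amplicon is
        # designed so the two mates read the same span)
        for (seq1, _q1), (seq2, _q2) in read_pairs:
            r2 = revcomp(seq2.upper())
            n = min(len(seq1), len(r2))
            s1, s2 = seq1.upper()[:n], r2[:n]
            overlap_bases += n
            mismatches += sum(a != b for a, b in zip(s1, s2))
        if overlap_bases == 0:
            raw = math.nan
        else:
            raw = mismatches / overlap_bases

    calling = math.nan
    if variant_counts is not None:
        if constant_region_span is None:
            raise ValueError("constant_region_span required with variant_counts")
        lo, hi = constant_region_span
        groups: dict[str, dict[str, int]] = {}
        for seq, cnt in variant_counts.items():
            var_key = seq[:lo] + seq[hi:]
            groups.setdefault(var_key, {})[seq[lo:hi]] = (
                groups.setdefault(var_key, {}).get(seq[lo:hi], 0) + cnt
            )
        miscalled = 0
        total = 0
        for crs in groups.values():
            modal = max(crs, key=lambda c: crs[c])
            for cseq, cnt in crs.items():
                total += cnt
                if cseq == modal:
                    continue
                res = edlib.align(cseq, modal, mode="NW", task="distance", k=1)
                if res["editDistance"] == 1:
                    miscalled += cnt
        if total:
            calling = miscalled / (total * (hi - lo))

    rates = ErrorRates(raw_per_nt=raw, calling_per_nt=calling)
    if n_possible_single_mutants is not None and read_length is not None:
        per_nt = calling if not math.isnan(calling) else raw
        frac_miscalled = miscalled_read_fraction(per_nt, read_length)
        rates.miscalled_variant_frequency = expected_miscalled_variant_frequency(
            frac_miscalled, n_possible_single_mutants
        )
        if n_library_variants is not None:
            rates.real_variant_frequency = expected_real_variant_frequency(
                1.0 - frac_miscalled, n_library_variants
            )
    return rates


def miscalled_read_fraction(per_nt_rate: float, length: int) -> float:
    """Fraction of reads carrying at least one miscalled nucleotide (~ rate x length)."""
    return per_nt_rate * length


def expected_miscalled_variant_frequency(
    miscalled_read_fraction: float, n_possible_single_mutants: int
) -> float:
    """Expected frequency of one specific miscalled variant."""
    return miscalled_read_fraction / n_possible_single_mutants


def expected_real_variant_frequency(
    correct_read_fraction: float, n_library_variants: int
) -> float:
    """Expected frequency of one real library variant."""
    return correct_read_fraction / n_library_variants


@dataclass
class TemplateSwitchEstimate:
    percent_free: float
    n_variants: int
    n_flagged: int


@dataclass(frozen=True)
class InsertionRecord:
    """A variant carrying a >= 2 nt insertion on one of its variable halves."""

    variant_id: str
    half: str  # 'L' or 'R'
    offset: int
    inserted: str
    other_half: str


def template_switch_free_fraction(
    records: Iterable[InsertionRecord],
) -> TemplateSwitchEstimate:
    """Estimate the fraction of variants free of PCR template switching.

    Insertions of two or more nucleotides are rare synthesis errors, so the
    same insertion signature appearing with two different other-halves marks
    a template-switch product; both members of a sharing pair are flagged.
    """
    records = list(records)
    if not records:
        raise ValueError("no insertion-bearing variants: estimate undefined")
    groups: dict[tuple[str, int, str], dict[str, set[str]]] = {}
    for r in records:
        if len(r.inserted) < 2:
            raise ValueError("insertion signatures must be >= 2 nt")
        key = (r.half, r.offset, r.inserted)
        groups.setdefault(key, {}).setdefault(r.other_half, set()).add(r.variant_id)
    flagged: set[str] = set()
    for by_other in groups.values():
        if len(by_other) >= 2:
            for ids in by_other.values():
                flagged.update(ids)
    n_variants = len({r.variant_id for r in records})
    pct = 100.0 * (1.0 - len(flagged) / n_variants)
    return TemplateSwitchEstimate(pct, n_variants, len(flagged))


# ---------------------------------------------------------------------------
# frequency tables
# ---------------------------------------------------------------------------

def compute_frequencies(
    rct: ReadCountTable, min_reads_per_replicate: int = 10
) -> FrequencyTable:
    """Nucleotide-level frequency table with the outlier-robust consensus.

    Genotypes are retained only if present in all four replicates with at
    least ``min_reads_per_replicate`` reads summed across the three time
    points in each replicate.  The consensus frequency per timepoint is the
    mean over the four replicate frequencies, replaced by the median when
    |mean - median| exceeds the median.
    """
    reps = sorted({r for r, _ in rct.counts.columns})
    if len(reps) != 4:
        raise ValueError(f"expected 4 replicates, found {reps}")
    depths = rct.depths
    counts = rct.counts
    per_rep_totals = counts.T.groupby(level="rep").sum().T
    keep = (per_rep_totals >= min_reads_per_replicate).all(axis=1)
    counts = counts.loc[keep]

    freqs = counts / depths
    consensus = {}
    for t in TIMEPOINTS:
        block = freqs.xs(t, axis=1, level="t")
        mean = block.mean(axis=1)
        median = block.median(axis=1)
        use_median = (mean - median).abs() > median
        consensus[t] = mean.where(~use_median, median)
    rep_freqs = freqs.copy()
    rep_freqs.columns = pd.MultiIndex.from_tuples(
        list(freqs.columns), names=["rep", "t"]
    )
    return FrequencyTable(
        rep_freqs=rep_freqs,
        consensus=pd.DataFrame(consensus),
        depths=depths,
        level="nt",
    )


def merge_amino_acid(
    ft: FrequencyTable, translations: Mapping[str, str], drop_untranslated: bool = True
) -> FrequencyTable:
    """Merge synonymous nucleotide genotypes into amino-acid genotypes.

    Frequencies and variances are summed over the synonymous variants.
    Amino-acid genotypes whose consensus trajectory matches one of the
    implausible appearance patterns (0,0,>0), (0,>0,0) or (>0,0,>0) are
    removed; the dropout pattern (>0, 0, 0) is retained and handled later as
    a boundary estimate.
    """
    if ft.level != "nt":
        raise ValueError("merge_amino_acid expects a nucleotide-level table")
    idx = ft.consensus.index
    missing = [g for g in idx if g not in translations]
    if missing and not drop_untranslated:
        raise KeyError(f"missing translation for {len(missing)} genotypes")
    keep = idx.difference(missing)
    aa = pd.Series({g: translations[g] for g in keep})

    consensus = ft.consensus.loc[keep].groupby(aa).sum()
    rep_freqs = ft.rep_freqs.loc[keep].groupby(aa).sum()
    variance = (
        ft.variance.loc[keep].groupby(aa).sum() if ft.variance is not None else None
    )
    n_syn = aa.groupby(aa).size()

    f0, f1, f2 = (consensus[t] for t in TIMEPOINTS)
    bad = ((f0 == 0) & (f1 == 0) & (f2 > 0)) | \
          ((f0 == 0) & (f1 > 0) & (f2 == 0)) | \
          ((f0 > 0) & (f1 == 0) & (f2 > 0))
    kept = consensus.index[~bad]

    return FrequencyTable(
        rep_freqs=rep_freqs.loc[kept],
        consensus=consensus.loc[kept],
        depths=ft.depths,
        level="aa",
        variance=variance.loc[kept] if variance is not None else None,
        n_synonyms=n_syn.loc[kept],
    )
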