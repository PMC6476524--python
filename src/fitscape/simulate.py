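"""Bulk-competition simulator with known ground truth.

The experiment being emulated: a pooled library of nucleotide variants grows
under selection; the pool is sampled by sequencing at three time points (t0,
t1, t14) in a 2-biological x 2-technical replicate design.  Cell numbers grow
exponentially, n_x(t) = n_x(0)·exp(s_x·t), so genotype frequencies follow
f_x(t) ∝ f_x(0)·exp(s_x·t) after renormalisation.  Biological drift perturbs
frequencies once per biological replicate (shared by its two technical
replicates); each technical replicate is an independent multinomial sample of
reads at the stated depth; per-nucleotide sequencing errors and rare PCR
template switching corrupt reads after sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fitscape.library import SegmentLibrary
from fitscape.reads import ReadCountTable

#: replicate -> biological replicate (reps 1,2 share bio rep 1; reps 3,4 share 2)
BIO_REP = {1: 1, 2: 1, 3: 2, 4: 2}
NUCLEOTIDES = "ACGT"


@dataclass
class CompetitionParams:
    """Study-design parameters of one simulated bulk competition.

    Defaults mirror the real design: three sampled time points in units of
    the first growth interval (t0 = 0, t1 = 1, t14 = 14), four replicates
    at ~10^6 reads each, mild biological drift, and small per-read error
    and template-switching rates.
    """

    n0_cells: int = 10_000_000
    depth_per_replicate_timepoint: int = 1_000_000
    timepoints: tuple[float, float, float] = (0.0, 1.0, 14.0)
    biological_drift_sd: float = 0.05
    per_nt_error_rate: float = 0.001
    template_switch_rate: float = 1e-4
    seed: int = 0
    #: replace multinomial sampling by largest-remainder rounding of the
    #: expected counts (noise-free limit; drift/error rates of 0 make the
    #: whole simulation deterministic)
    exact_counts: bool = False

    def __post_init__(self):
        for p in (self.per_nt_error_rate, self.template_switch_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must be probabilities in [0, 1]")
        if self.depth_per_replicate_timepoint <= 0:
            raise ValueError("depth must be positive")
        if self.biological_drift_sd < 0:
            raise ValueError("biological_drift_sd must be >= 0")


def simulate_competition(
    lib: SegmentLibrary,
    true_fitness: dict[str, float],
    params: CompetitionParams,
    initial_frequencies: np.ndarray | None = None,
) -> ReadCountTable:
    """Simulate read counts for every replicate x time point.

    ``true_fitness`` maps amino-acid genotypes to growth rates s >= 0
    (0 = lethal, ~1 = neutral).  Counts sum exactly to the configured depth
    in each replicate x time point.
    """
    variants = lib.nt_variants
    n = len(variants)
    s = np.array([true_fitness[v.aa] for v in variants], float)
    if np.any(s < 0):
        raise ValueError("true fitness must be non-negative")

    # independent streams: founder pool, per-bio-rep drift, per-replicate sampling
    root = np.random.SeedSequence(params.seed)
    rng_founder, rng_b1, rng_b2, *rep_seeds = [
        np.random.default_rng(s_) for s_ in root.spawn(3 + 12)
    ]

    if initial_frequencies is None:
        f_init = np.full(n, 1.0 / n)
    else:
        f_init = np.asarray(initial_frequencies, float)
        f_init = f_init / f_init.sum()
    if params.exact_counts:
        f0 = f_init
    else:
        # library bottleneck: one founder pool shared by both biological replicates
        founders = rng_founder.multinomial(params.n0_cells, f_init)
        f0 = founders / founders.sum()

    seqs = [v.nt for v in variants]
    halves = {v.nt: lib.split_halves(v.nt) for v in variants}
    cr = lib.constant_region

    tables: dict[tuple[int, int], dict[str, int]] = {}
    stream = iter(rep_seeds)
    for bio, rng_drift in ((1, rng_b1), (2, rng_b2)):
        # genetic drift accumulates through the competition as a Brownian
        # perturbation of per-genotype log frequency, shared by the two
        # technical replicates of this biological replicate: one increment
        # for the pre-competition growth and one per elapsed interval
        drift = {}
        if params.biological_drift_sd > 0:
            eps = rng_drift.normal(0.0, params.biological_drift_sd, size=n)
            prev_t = None
            for t in params.timepoints:
                if prev_t is not None:
                    dt = t - prev_t
                    eps = eps + rng_drift.normal(
                        0.0, params.biological_drift_sd * np.sqrt(dt), size=n
                    )
                drift[t] = eps
                prev_t = t
        for rep in [r for r, b in BIO_REP.items() if b == bio]:
            for ti, t in enumerate(params.timepoints):
                rng = next(stream)
                w = f0 * np.exp(s * t)
                if drift:
                    w = w * np.exp(drift[t])
                freq = w / w.sum()
                depth = params.depth_per_replicate_timepoint
                if params.exact_counts:
                    counts = _round_to_depth(freq, depth)
                else:
                    counts = rng.multinomial(depth, freq)
                table = {seq: int(c) for seq, c in zip(seqs, counts) if c}
                if params.template_switch_rate > 0:
                    _template_switch(table, params.template_switch_rate, halves, cr, rng)
                if params.per_nt_error_rate > 0:
                    _sequencing_errors(table, params.per_nt_error_rate, rng)
                tables[(rep, ti)] = table

    return ReadCountTable.from_dicts(tables)


def _round_to_depth(freq: np.ndarray, depth: int) -> np.ndarray:
    """Largest-remainder rounding of expected counts to sum exactly to depth."""
    expected = freq * depth
    counts = np.floor(expected).astype(np.int64)
    short = depth - counts.sum()
    if short > 0:
        order = np.argsort(expected - counts)[::-1]
        counts[order[:short]] += 1
    return counts


def _template_switch(table, rate, halves, constant_region, rng):
    """Replace a Binomial(depth, rate) number of reads by left/right chimeras.

    The left half comes from the read being replaced; the right half is
    drawn frequency-weighted from the pool, matching the two-block amplicon
    structure in which recombination happens within the constant region.
    """
    seqs = list(table)
    counts = np.array([table[q] for q in seqs])
    depth = counts.sum()
    n_switch = rng.binomial(depth, rate)
    if n_switch == 0:
        return
    left_counts = rng.multivariate_hypergeometric(counts, n_switch)
    right_idx = rng.choice(len(seqs), size=n_switch, p=counts / depth)
    j = 0
    for i, m in enumerate(left_counts):
        if m == 0:
            continue
        left, _ = halves[seqs[i]]
        table[seqs[i]] -= int(m)
        for r in right_idx[j : j + m]:
            _, right = halves[seqs[r]]
            chimera = left + constant_region + right
            table[chimera] = table.get(chimera, 0) + 1
        j += m
    for q in [q for q, c in table.items() if c == 0]:
        del table[q]


def _sequencing_errors(table, rate, rng):
    """Substitute one random nucleotide in a Binomial-distributed subset of reads.

    The per-read miscall probability is 1-(1-rate)^L; multiple errors per
    read are rare at the simulated rates and are not modelled.
    """
    for seq in list(table):
        c = table[seq]
        length = len(seq)
        p_read = 1.0 - (1.0 - rate) ** length
        n_err = rng.binomial(c, p_read)
        if n_err == 0:
            continue
        pos = rng.integers(0, length, size=n_err)
        alt = rng.integers(0, 3, size=n_err)
        table[seq] = c - int(n_err)
        for p, a in zip(pos, alt):
            others = [b for b in NUCLEOTIDES if b != seq[p]]
            mutated = seq[:p] + others[a] + seq[p + 1 :]
            table[mutated] = table.get(mutated, 0) + 1
        if table[seq] == 0:
            del table[seq]
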