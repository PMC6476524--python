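"""Canonical simulated study conditions.

These configurations define the simulated experiments used throughout the
test suite, the examples and the acceptance analyses: an 8-site combinatorial
segment (~6,000 amino-acid genotypes, ~12,000 nucleotide variants) competing
at 10^6 reads per replicate x time point, planted cliff landscapes for the
fitness-potential model, additive and interaction landscapes for the
sign-epistasis analyses, and a synonym-rich segment for the synonymous-
variant false-discovery-rate analysis.  Sizes are chosen so that every
analysis runs on a single CPU in minutes while preserving the statistical
structure of a library-scale experiment.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from fitscape.landscape import CliffFunction, GroundTruthLandscape
from fitscape.library import SegmentLibrary, build_library
from fitscape.simulate import CompetitionParams

#: Variable sites of the standard simulated segment (first state = wildtype).
#: The degenerate codons of several sites produce non-extant byproducts and
#: premature stops, as in a real degenerate-codon library.
SEGMENT_STATES = [
    ["Y", "Q"],
    ["F", "W"],
    ["D", "E", "N"],
    ["G", "R", "S"],
    ["L", "V", "M"],
    ["A", "V"],
    ["S", "T"],
    ["H", "N"],
]

#: Site vocabulary for the fitness-potential analyses (3,456 genotypes).
POTENTIAL_VOCAB = [
    ["A", "V"],
    ["L", "I", "M"],
    ["S", "T", "N"],
    ["K", "R"],
    ["D", "E"],
    ["G", "A", "S"],
    ["F", "W"],
    ["H", "N"],
    ["P", "Q"],
    ["C", "W"],
]


def standard_segment() -> SegmentLibrary:
    """The standard simulated segment library."""
    return build_library(SEGMENT_STATES, segment_id="sim-segment")


def standard_params(seed: int, depth: int = 1_000_000) -> CompetitionParams:
    """Competition parameters mirroring the real study design."""
    return CompetitionParams(
        depth_per_replicate_timepoint=depth,
        timepoints=(0.0, 1.0, 14.0),
        biological_drift_sd=0.05,
        per_nt_error_rate=0.001,
        template_switch_rate=1e-4,
        seed=seed,
    )


def segment_landscape(seed: int) -> GroundTruthLandscape:
    """Random unidimensional cliff landscape over the standard segment's states.

    Penalties |N(0, 1.1)| against a threshold of 2.5 put roughly half of the
    genotypes on the plateau and the rest on or over the cliff, mimicking the
    bimodal fitness distributions of real segments.
    """
    from fitscape.landscape import random_landscape

    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    return random_landscape(
        standard_segment(), rng, coeff_scale=1.1,
        cliff=CliffFunction(plateau=1.0, threshold=2.5, steepness=0.3),
    )


def potential_genotypes() -> list[str]:
    return ["".join(c) for c in itertools.product(*POTENTIAL_VOCAB)]


def _draw_coeffs(rng, scale: float, signed: bool) -> dict[tuple[int, str], float]:
    out = {}
    for i, states in enumerate(POTENTIAL_VOCAB):
        for s in states[1:]:
            c = rng.normal(0.0, scale)
            out[(i + 1, s)] = float(c if signed else abs(c))
    return out


def unidimensional_landscape(seed: int) -> GroundTruthLandscape:
    """Planted single-potential cliff landscape on POTENTIAL_VOCAB."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 201]))
    return GroundTruthLandscape(
        coefficients=_draw_coeffs(rng, 0.7, signed=False),
        threshold_function=CliffFunction(1.0, 1.8, 0.3),
    )


def two_potential_landscape(seed: int) -> GroundTruthLandscape:
    """Planted two-potential landscape: the product of two cliffs.

    The two potentials have disjoint site support (sites 1-5 vs 6-10 with
    penalties cycling 0.4/0.8/1.2) plus a small seeded jitter, so fitness
    is the AND of two independent threshold constraints — a shape no single
    linear potential can order, whatever the jitter draw.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    cliff = CliffFunction(1.0, 1.6, 0.4)
    cycle = [0.4, 0.8, 1.2]
    c1: dict[tuple[int, str], float] = {}
    c2: dict[tuple[int, str], float] = {}
    rank = 0
    for i, states in enumerate(POTENTIAL_VOCAB):
        for s in states[1:]:
            target = c1 if i < len(POTENTIAL_VOCAB) // 2 else c2
            target[(i + 1, s)] = cycle[rank % 3] + float(rng.normal(0.0, 0.05))
            rank += 1
    return GroundTruthLandscape(
        coefficients=c1, threshold_function=cliff,
        extra_potentials=[(c2, cliff)],
    )


# ---------------------------------------------------------------------------
# sign-epistasis study conditions
# ---------------------------------------------------------------------------

#: Two-state sites used for the sign-epistasis analyses (256 genotypes would
#: be too few; ten sites give 3,456 backgrounds via POTENTIAL_VOCAB).
SIGN_VOCAB = POTENTIAL_VOCAB

EFFECT_NOISE_SD = 0.1  # measurement noise on rescaled fitness


def additive_fitness_table(seed: int, noise_sd: float = EFFECT_NOISE_SD) -> pd.Series:
    """Epistasis-free landscape: small additive penalties plus noise.

    Every replacement shifts fitness by the same small amount in every
    background, so any sign-epistasis call on this table is a false
    positive.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 301]))
    genos = ["".join(c) for c in itertools.product(*SIGN_VOCAB)]
    penalties = {
        (i, s): float(rng.uniform(0.0, 0.02))
        for i, states in enumerate(SIGN_VOCAB)
        for s in states[1:]
    }
    base = np.array(
        [1.0 - sum(penalties.get((i, a), 0.0) for i, a in enumerate(g)) for g in genos]
    )
    noisy = base + rng.normal(0.0, noise_sd, size=len(genos))
    return pd.Series(np.clip(noisy, 0.0, None), index=genos)


#: Planted interactions: a reciprocal sign-epistasis pair between sites 0 and
#: 3 and a unidirectional interaction in which site 8's state flips the sign
#: of site 6's replacement while site 6 modulates only the magnitude of
#: site 8's (keeping its positive effects below the 0.4 cutoff).
RECIPROCAL_SITES = (0, 3)   # (A->V) x (K->R)
UNIDIRECTIONAL_SITES = (6, 8)  # focal (F->W) modulated by (P->Q)


def planted_sign_fitness_table(seed: int, noise_sd: float = EFFECT_NOISE_SD) -> pd.Series:
    """Fitness table with one reciprocal and one unidirectional sign interaction."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 302]))
    genos = ["".join(c) for c in itertools.product(*SIGN_VOCAB)]
    i, j = RECIPROCAL_SITES
    u, v = UNIDIRECTIONAL_SITES
    alt_i = SIGN_VOCAB[i][1]
    alt_j = SIGN_VOCAB[j][1]
    alt_u = SIGN_VOCAB[u][1]
    alt_v = SIGN_VOCAB[v][1]
    vals = np.empty(len(genos))
    for r, g in enumerate(genos):
        f = 1.0
        # reciprocal pair: either replacement is lethal alone, rescued jointly
        if (g[i] == alt_i) != (g[j] == alt_j):
            f -= 1.0
        # unidirectional interaction: the focal replacement at u is
        # deleterious on the v-wildtype background and beneficial on the
        # v-mutant background, while v's own effect on the u-mutant
        # background (-0.15) never crosses the large-effect cutoff, so only
        # the u -> v direction is detectable
        if g[v] != alt_v and g[u] == alt_u:
            f -= 0.5
        elif g[v] == alt_v:
            f -= 1.0 if g[u] != alt_u else 0.65
        vals[r] = f
    vals = vals + rng.normal(0.0, noise_sd, size=len(genos))
    return pd.Series(np.clip(vals, 0.0, None), index=genos)


# ---------------------------------------------------------------------------
# synonym-rich segment for the synonymous FDR analysis
# ---------------------------------------------------------------------------

#: Four L/V/M sites give most genotypes 4-16 synonymous codon combinations
#: (needed for the n = 1..10 synonymous-subset analysis); the Y/Q site's
#: degenerate codon includes TAA, providing nonsense genotypes.
FDR_STATES = [
    ["L", "V", "M"],
    ["Y", "Q"],
    ["L", "V", "M"],
    ["L", "V", "M"],
    ["L", "V", "M"],
]


def fdr_segment() -> SegmentLibrary:
    """Small segment whose degenerate codons give 1-16 synonyms per genotype."""
    return build_library(FDR_STATES, segment_id="sim-fdr")


def fdr_landscape() -> GroundTruthLandscape:
    """Fixed gentle-cliff landscape for the synonymous-FDR analysis.

    Designed with two features the analysis depends on: a well-populated
    neutral plateau (several zero- and near-zero-penalty states), so the
    rescaling's mode anchor is sharp, and a dense band of moderately
    deleterious genotypes on the cliff — the regime where a single
    nucleotide variant drops out of the final time point while its merged
    amino-acid genotype does not, which is where synonymous-subset refits
    actually disagree.
    """
    lib = fdr_segment()
    wt = lib.wildtype_aa
    states = set()
    for v in lib.nt_variants:
        if not v.is_nonsense:
            states.update(zip(lib.sites, v.aa))
    penalty_cycle = [0.0, 0.0, 0.3, 0.5, 0.8, 1.1, 1.7]
    coeffs = {}
    for rank, (site, aa) in enumerate(sorted(states)):
        if aa == wt[lib.sites.index(site)]:
            continue
        coeffs[(site, aa)] = penalty_cycle[rank % len(penalty_cycle)]
    return GroundTruthLandscape(
        coefficients=coeffs,
        threshold_function=CliffFunction(plateau=1.0, threshold=2.2, steepness=0.35),
    )
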