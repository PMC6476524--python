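"""Landscape-topology statistics: accessible paths and unfit-genotype clustering.

Between two fit parental genotypes at Hamming distance d there are 2^d - 2
intermediate genotypes (each differing site taken from either parent) and at
most d! shortest paths.  Representing measured genotypes as vertices of the
Hamming graph (edges = one replacement apart), shortest paths are counted by
dynamic programming over breadth-first layers; removing unfit vertices
(rescaled fitness 0) leaves the accessible paths.  Null models redistribute
the same number of unfit genotypes at random.  Clustering of unfit genotypes
is quantified by mean vertex degree of the unfit-induced subgraph against
random same-size subsets, and inter- vs intra-segmental epistasis by
comparing the proportion of unfit intermediates between fit pairs with the
proportion of unfit genotypes by distance from a reference genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from typing import Iterable, Mapping

import numpy as np
import pandas as pd


@dataclass
class PathStats:
    parents: tuple[str, str]
    hamming_distance: int
    n_intermediates_total: int
    n_intermediates_measured: int
    n_paths_total: int
    n_paths_accessible: int
    null_mean: float | None = None
    null_sd: float | None = None

    @property
    def fraction_accessible(self) -> float:
        if self.n_paths_total == 0:
            return float("nan")
        return self.n_paths_accessible / self.n_paths_total


@dataclass
class ConnectivityStats:
    mean_degree_all: float
    mean_degree_unfit: float
    random_mean: float
    random_sd: float
    draws: int = 1000


def hamming(g1: str, g2: str) -> int:
    if len(g1) != len(g2):
        raise ValueError("genotypes differ in length")
    return sum(a != b for a, b in zip(g1, g2))


def _differing_sites(g1: str, g2: str) -> list[int]:
    return [i for i, (a, b) in enumerate(zip(g1, g2)) if a != b]


def _genotype_from_mask(g1: str, g2: str, sites: list[int], mask: int) -> str:
    out = list(g1)
    for bit, site in enumerate(sites):
        if mask >> bit & 1:
            out[site] = g2[site]
    return "".join(out)


def intermediates(
    g1: str, g2: str, measured: Iterable[str] | None = None
) -> tuple[list[str], list[str]]:
    """All 2^d - 2 intermediates between two genotypes, and the measured subset."""
    sites = _differing_sites(g1, g2)
    d = len(sites)
    if d == 0:
        raise ValueError("parental genotypes are identical")
    all_inter = [
        _genotype_from_mask(g1, g2, sites, mask) for mask in range(1, 2**d - 1)
    ]
    if measured is None:
        return all_inter, all_inter
    measured = set(measured)
    return all_inter, [g for g in all_inter if g in measured]


def _count_paths(d: int, present_masks: set[int]) -> int:
    """Shortest (length-d) paths from mask 0 to mask 2^d-1 through present vertices.

    Dynamic programming over layers of the d-hypercube: the number of paths
    into a vertex is the sum over its present lower neighbours; endpoints
    are always present.
    """
    full = (1 << d) - 1
    paths = {0: 1}
    order = sorted(range(1, full + 1), key=lambda m: m.bit_count())
    for mask in order:
        if mask != full and mask not in present_masks:
            continue
        total = 0
        m = mask
        while m:
            bit = m & -m
            total += paths.get(mask ^ bit, 0)
            m ^= bit
        if total:
            paths[mask] = total
    return paths.get(full, 0)


def accessible_path_fraction(
    g1: str,
    g2: str,
    fitness: Mapping[str, float],
    fit_threshold: float = 0.6,
    unfit_value: float = 0.0,
    require_fit_parents: bool = True,
) -> PathStats:
    """Count shortest paths among measured intermediates, with and without unfit ones.

    Genotypes absent from ``fitness`` are unmeasured: they are missing
    vertices and break paths.  "Unfit" means rescaled fitness equal to
    ``unfit_value`` (0); parents must have fitness >= ``fit_threshold``.
    """
    if require_fit_parents:
        for g in (g1, g2):
            if g not in fitness or fitness[g] < fit_threshold:
                raise ValueError(f"parent {g} is not a fit measured genotype")
    sites = _differing_sites(g1, g2)
    d = len(sites)
    if d == 0:
        raise ValueError("parental genotypes are identical")
    measured_masks = {
        mask
        for mask in range(1, 2**d - 1)
        if _genotype_from_mask(g1, g2, sites, mask) in fitness
    }
    fit_masks = {
        mask
        for mask in measured_masks
        if fitness[_genotype_from_mask(g1, g2, sites, mask)] > unfit_value
    }
    return PathStats(
        parents=(g1, g2),
        hamming_distance=d,
        n_intermediates_total=2**d - 2,
        n_intermediates_measured=len(measured_masks),
        n_paths_total=_count_paths(d, measured_masks),
        n_paths_accessible=_count_paths(d, fit_masks),
    )


def random_null_paths(
    g1: str,
    g2: str,
    measured_intermediates: Iterable[str],
    n_unfit: int,
    draws: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Accessible-path fraction when ``n_unfit`` intermediates are unfit at random.

    Returns the mean and standard deviation over draws of the fraction of
    shortest paths that avoid the randomly drawn unfit intermediates.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sites = _differing_sites(g1, g2)
    d = len(sites)
    measured_masks = []
    inter_index = {}
    for mask in range(1, 2**d - 1):
        g = _genotype_from_mask(g1, g2, sites, mask)
        inter_index[g] = mask
    measured_masks = [inter_index[g] for g in measured_intermediates]
    if n_unfit > len(measured_masks):
        raise ValueError("n_unfit exceeds the number of measured intermediates")
    total = _count_paths(d, set(measured_masks))
    if total == 0:
        return float("nan"), float("nan")
    fractions = np.empty(draws)
    masks_arr = np.array(measured_masks)
    for i in range(draws):
        unfit = set(rng.choice(masks_arr, size=n_unfit, replace=False)) if n_unfit else set()
        acc = _count_paths(d, set(measured_masks) - unfit)
        fractions[i] = acc / total
    return float(fractions.mean()), float(fractions.std())


# ---------------------------------------------------------------------------
# connectivity of unfit genotypes
# ---------------------------------------------------------------------------

def _degree_sum(genotypes: Iterable[str]) -> tuple[int, int]:
    """Total degree and vertex count of the 1-replacement graph on a genotype set.

    Degrees are computed by bucketing genotypes on each site-masked key:
    a bucket of size m is a clique contributing m-1 to each member.
    """
    genotypes = list(genotypes)
    if not genotypes:
        return 0, 0
    n_sites = len(genotypes[0])
    total = 0
    for site in range(n_sites):
        buckets: dict[str, int] = {}
        for g in genotypes:
            key = g[:site] + "\x00" + g[site + 1 :]
            buckets[key] = buckets.get(key, 0) + 1
        total += sum(m * (m - 1) for m in buckets.values())
    return total, len(genotypes)


def unfit_connectivity(
    measured: Iterable[str],
    unfit: Iterable[str],
    draws: int = 1000,
    seed: int | np.random.Generator = 0,
) -> ConnectivityStats:
    """Mean vertex degree: all measured genotypes, unfit subgraph, random subsets.

    The random reference redistributes the same number of genotypes
    uniformly among the measured set, averaged over ``draws`` runs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    measured = list(measured)
    unfit = list(unfit)
    if not set(unfit) <= set(measured):
        raise ValueError("unfit genotypes must be a subset of measured genotypes")
    deg_sum, n = _degree_sum(measured)
    mean_all = deg_sum / n if n else 0.0
    if not unfit:
        return ConnectivityStats(mean_all, 0.0, 0.0, 0.0, draws)
    deg_sum_u, n_u = _degree_sum(unfit)
    mean_unfit = deg_sum_u / n_u

    measured_arr = np.array(measured)
    means = np.empty(draws)
    for i in range(draws):
        sub = rng.choice(measured_arr, size=n_u, replace=False)
        ds, m = _degree_sum(sub)
        means[i] = ds / m
    return ConnectivityStats(
        mean_degree_all=mean_all,
        mean_degree_unfit=mean_unfit,
        random_mean=float(means.mean()),
        random_sd=float(means.std()),
        draws=draws,
    )


# ---------------------------------------------------------------------------
# intra- vs inter-segmental epistasis
# ---------------------------------------------------------------------------

@dataclass
class IntraInterCurves:
    intra: pd.Series  # proportion of unfit intermediates vs pair Hamming distance
    total: pd.Series  # proportion of unfit genotypes vs distance from reference
    ratio: pd.Series  # total / intra per distance
    n_pairs: pd.Series = field(default_factory=pd.Series)


def intra_vs_inter(
    fitness: Mapping[str, float],
    reference: str,
    fit_threshold: float = 0.6,
    unfit_value: float = 0.0,
    max_pairs: int = 2000,
    min_bin: int = 10,
    seed: int | np.random.Generator = 0,
) -> IntraInterCurves:
    """Unfit-intermediate curves separating within-pair from background epistasis.

    Curve A (intra): over sampled pairs of fit genotypes, the proportion of
    measured intermediates that are unfit, binned by the pair's Hamming
    distance.  Curve B (total): the proportion of unfit genotypes among all
    measured genotypes at each distance from the reference.  Unfitness that
    only arises through interactions with the reference background inflates
    B relative to A; the per-distance ratio B/A quantifies it.  Distance
    bins with fewer than ``min_bin`` observations are suppressed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fitness = dict(fitness)
    if reference not in fitness:
        raise ValueError("reference genotype not in the fitness table")
    genotypes = list(fitness)
    fit_set = [g for g in genotypes if fitness[g] >= fit_threshold]

    pairs = [(a, b) for i, a in enumerate(fit_set) for b in fit_set[i + 1 :]
             if a != b]
    if len(pairs) > max_pairs:
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]

    unfit_frac: dict[int, list[float]] = {}
    for a, b in pairs:
        d = hamming(a, b)
        if d < 2:
            continue
        _, measured = intermediates(a, b, measured=fitness)
        if not measured:
            continue
        frac = np.mean([fitness[g] <= unfit_value for g in measured])
        unfit_frac.setdefault(d, []).append(float(frac))

    intra = {
        d: float(np.mean(v)) for d, v in unfit_frac.items() if len(v) >= min_bin
    }
    n_pairs = {d: len(v) for d, v in unfit_frac.items() if len(v) >= min_bin}

    by_dist: dict[int, list[str]] = {}
    for g in genotypes:
        by_dist.setdefault(hamming(g, reference), []).append(g)
    total = {
        d: float(np.mean([fitness[g] <= unfit_value for g in v]))
        for d, v in by_dist.items()
        if len(v) >= min_bin and d > 0
    }

    common = sorted(set(intra) & set(total))
    ratio = {
        d: (total[d] / intra[d]) if intra[d] > 0 else float("inf") for d in common
    }
    return IntraInterCurves(
        intra=pd.Series(intra).sort_index(),
        total=pd.Series(total).sort_index(),
        ratio=pd.Series(ratio).sort_index(),
        n_pairs=pd.Series(n_pairs).sort_index(),
    )


def max_shortest_paths(d: int) -> int:
    """Upper bound d! on the number of shortest paths at Hamming distance d."""
    out = 1
    for i in range(2, d + 1):
        out *= i
    return out
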