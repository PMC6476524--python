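"""Per-replacement fitness effects across backgrounds and sign epistasis.

For an amino-acid replacement (site, a -> b), its fitness effect is computed
in every genetic background — the amino-acid states at all other sites — in
which both states were measured.  The fraction of backgrounds with a neutral
effect is the histogram-overlap between the effect distribution and the
synonymous-difference null; effects beyond +-0.4 count as strong beneficial /
deleterious and are reported as significant only above the corresponding
false discovery rate.  A replacement showing large effects of both signs is
tested for sign epistasis: secondary replacements that significantly alter
the ratio of large increases to large decreases (two-sided Fisher's exact
test, Bonferroni-corrected p < 0.05) become edges of the epistasis graph;
reciprocal sign epistasis means both directions are significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

Replacement = tuple[int, str, str]  # (site index, state_from, state_to)


@dataclass
class EffectProfile:
    replacement: Replacement
    backgrounds: list[str]
    deltas: np.ndarray
    neutral: float | None = None
    beneficial: float | None = None
    deleterious: float | None = None
    passes_fdr_beneficial: bool | None = None
    passes_fdr_deleterious: bool | None = None

    @property
    def empty(self) -> bool:
        return len(self.deltas) == 0


def _background(genotype: str, site: int) -> str:
    return genotype[:site] + genotype[site + 1 :]


def replacement_effects(
    fitness: pd.Series, site: int, state_from: str, state_to: str
) -> EffectProfile:
    """Fitness effect of one replacement in every shared background.

    ``fitness`` maps amino-acid genotype strings to (rescaled) fitness;
    ``site`` is the 0-based position within the genotype string.  Returns a
    (possibly empty) profile of delta = s(to) - s(from) over backgrounds in
    which both states were measured.
    """
    with_from: dict[str, float] = {}
    with_to: dict[str, float] = {}
    for g, f in fitness.items():
        st = g[site]
        if st == state_from:
            with_from[_background(g, site)] = f
        elif st == state_to:
            with_to[_background(g, site)] = f
    shared = sorted(set(with_from) & set(with_to))
    deltas = np.array([with_to[b] - with_from[b] for b in shared])
    return EffectProfile((site, state_from, state_to), shared, deltas)


def overlap_coefficient(x: np.ndarray, y: np.ndarray, bin_width: float = 0.05) -> float:
    """Histogram overlap sum(min(p_i, q_i)) on common bins spanning both samples."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    edges = np.arange(lo - bin_width, hi + 2 * bin_width, bin_width)
    p, _ = np.histogram(x, bins=edges)
    q, _ = np.histogram(y, bins=edges)
    return float(np.minimum(p / p.sum(), q / q.sum()).sum())


def neutral_fraction(
    profile: EffectProfile,
    null_deltas: np.ndarray,
    threshold: float = 0.4,
    bin_width: float = 0.05,
    fdr_beneficial: float = 0.0,
    fdr_deleterious: float = 0.0,
) -> EffectProfile:
    """Classify a profile into neutral / beneficial / deleterious fractions.

    The neutral fraction is the overlap between the background-effect
    distribution and the synonymous (measurement-noise) null; large-effect
    fractions use the +-``threshold`` cutoffs and are flagged significant
    when they exceed the supplied false discovery rates.
    """
    if profile.empty:
        raise ValueError("empty effect profile: no shared backgrounds")
    profile.neutral = overlap_coefficient(profile.deltas, null_deltas, bin_width)
    profile.beneficial = float(np.mean(profile.deltas > threshold))
    profile.deleterious = float(np.mean(profile.deltas < -threshold))
    profile.passes_fdr_beneficial = profile.beneficial > fdr_beneficial
    profile.passes_fdr_deleterious = profile.deleterious > fdr_deleterious
    return profile


@dataclass
class SignEpistasisTest:
    focal: Replacement
    secondary: Replacement
    table: np.ndarray  # 2x2: secondary state (from/to) x effect sign (up/down)
    p_raw: float
    p_bonferroni: float
    significant: bool


def detect_sign_epistasis(
    fitness: pd.Series,
    focal: Replacement,
    threshold: float = 0.4,
    alpha: float = 0.05,
    secondary_sites: list[int] | None = None,
) -> list[SignEpistasisTest]:
    """Secondary replacements that modulate the sign of a focal replacement.

    Backgrounds are partitioned into those where the focal replacement
    increases fitness by more than ``threshold`` and those where it
    decreases it by more than ``threshold``.  For every secondary site and
    ordered state pair, a 2x2 contingency table (secondary state x effect
    sign) is tested with a two-sided Fisher exact test; Bonferroni
    correction is over all secondary replacements tested for this focal.
    With no large-effect backgrounds of both signs no test is possible.
    """
    site, a, b = focal
    profile = replacement_effects(fitness, site, a, b)
    if profile.empty:
        return []
    up = [bg for bg, d in zip(profile.backgrounds, profile.deltas) if d > threshold]
    down = [bg for bg, d in zip(profile.backgrounds, profile.deltas) if d < -threshold]
    if not up or not down:
        return []

    n_sites = len(profile.backgrounds[0])
    # background strings index sites excluding the focal one
    bg_sites = [s for s in range(n_sites + 1) if s != site]
    if secondary_sites is not None:
        test_positions = [bg_sites.index(s) for s in secondary_sites if s in bg_sites]
    else:
        test_positions = list(range(n_sites))

    tests: list[SignEpistasisTest] = []
    for pos in test_positions:
        states = sorted({bg[pos] for bg in up} | {bg[pos] for bg in down})
        for x, y in combinations(states, 2):
            n_up_x = sum(bg[pos] == x for bg in up)
            n_up_y = sum(bg[pos] == y for bg in up)
            n_dn_x = sum(bg[pos] == x for bg in down)
            n_dn_y = sum(bg[pos] == y for bg in down)
            table = np.array([[n_up_x, n_dn_x], [n_up_y, n_dn_y]])
            if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
                continue
            _, p = fisher_exact(table, alternative="two-sided")
            tests.append(
                SignEpistasisTest(
                    focal=focal,
                    secondary=(bg_sites[pos], x, y),
                    table=table,
                    p_raw=float(p),
                    p_bonferroni=1.0,
                    significant=False,
                )
            )
    m = len(tests)
    for t in tests:
        t.p_bonferroni = min(1.0, t.p_raw * m)
        t.significant = t.p_bonferroni < alpha
    return tests


@dataclass
class EpistasisGraph:
    """Sign-epistasis network over state pairs at sites.

    Nodes are unordered extant state pairs at a site; a directed edge
    A -> B means the sign of A's fitness effect is modulated by B's state.
    Reciprocal edges exist where both directions are significant.
    """

    directed: nx.DiGraph
    summary: dict[str, float] = field(default_factory=dict)

    @property
    def reciprocal_pairs(self) -> set[tuple]:
        return {
            tuple(sorted((u, v)))
            for u, v in self.directed.edges
            if self.directed.has_edge(v, u)
        }


def _node(replacement: Replacement):
    site, a, b = replacement
    x, y = sorted((a, b))
    return (site, x, y)


def build_epistasis_graph(
    fitness: pd.Series,
    replacements: list[Replacement],
    n_sites: int | None = None,
    threshold: float = 0.4,
    alpha: float = 0.05,
) -> EpistasisGraph:
    """Run sign-epistasis detection for every replacement and assemble the graph.

    The summary reports the fraction of sites with any sign epistasis and
    with reciprocal sign epistasis, plus the fraction of site pairs linked
    by at least one significant interaction.
    """
    g = nx.DiGraph()
    for rep in replacements:
        g.add_node(_node(rep))
    for rep in replacements:
        for t in detect_sign_epistasis(fitness, rep, threshold=threshold, alpha=alpha):
            if t.significant:
                g.add_edge(_node(t.focal), _node(t.secondary), p=t.p_bonferroni)

    sites = {n[0] for n in g.nodes}
    n_sites = n_sites or len(sites)
    # a site is under sign epistasis iff one of its replacements has a
    # significant secondary, i.e. it is the source of a directed edge
    sites_with_sign = {u[0] for u, v in g.edges}
    graph = EpistasisGraph(directed=g)
    recip_sites = {n[0] for pair in graph.reciprocal_pairs for n in pair}
    site_pairs_linked = {tuple(sorted((u[0], v[0]))) for u, v in g.edges if u[0] != v[0]}
    n_pairs = n_sites * (n_sites - 1) // 2
    graph.summary = {
        "n_sites": n_sites,
        "sites_with_sign_epistasis": len(sites_with_sign),
        "sites_with_reciprocal": len(recip_sites),
        "fraction_sites_sign": len(sites_with_sign) / n_sites if n_sites else 0.0,
        "fraction_sites_reciprocal": len(recip_sites) / n_sites if n_sites else 0.0,
        "fraction_site_pairs": len(site_pairs_linked) / n_pairs if n_pairs else 0.0,
    }
    return graph


def extant_replacements(states_per_site: dict[int, list[str]], sites: list[int]) -> list[Replacement]:
    """All unordered extant state pairs per site, as 0-based replacements."""
    out = []
    for pos, site in enumerate(sites):
        for a, b in combinations(sorted(states_per_site[site]), 2):
            out.append((pos, a, b))
    return out
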