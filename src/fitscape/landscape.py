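"""Ground-truth fitness landscapes for simulation.

True fitness is generated from one or more *fitness potentials* — linear
combinations p = Σ cᵢxᵢ of indicator variables for amino-acid states — passed
through a monotone cliff-like threshold function: fitness stays at the
plateau while the potential is below the threshold and collapses towards
lethal beyond it (truncation selection).  Optional pairwise interaction terms
plant sign epistasis; additional potentials make the landscape
multidimensional by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from fitscape.codons import STOP
from fitscape.library import SegmentLibrary


@dataclass
class CliffFunction:
    """Monotone threshold map from potential to fitness.

    fitness(p) = plateau * sigmoid((threshold - p) / steepness): ≈ plateau
    for p well below the threshold, ≈ 0 well above it.  Coefficients are
    penalties (wildtype states contribute 0), so the wildtype sits at p = 0
    on the plateau.
    """

    plateau: float = 1.0
    threshold: float = 3.0
    steepness: float = 0.4

    def __call__(self, p):
        return self.plateau * expit((self.threshold - np.asarray(p, float)) / self.steepness)


@dataclass
class GroundTruthLandscape:
    """Planted genotype→fitness map used to validate the estimation pipeline."""

    coefficients: dict[tuple[int, str], float]
    threshold_function: CliffFunction = field(default_factory=CliffFunction)
    extra_potentials: list[tuple[dict[tuple[int, str], float], CliffFunction]] = field(
        default_factory=list
    )
    pairwise_terms: dict[tuple[int, str, int, str], float] = field(default_factory=dict)

    def potential(self, genotype: str, sites: list[int]) -> float:
        """Primary fitness potential of an amino-acid genotype (with pairwise terms)."""
        p = sum(
            self.coefficients.get((site, aa), 0.0)
            for site, aa in zip(sites, genotype)
        )
        for (s1, a1, s2, a2), c in self.pairwise_terms.items():
            i, j = sites.index(s1), sites.index(s2)
            if genotype[i] == a1 and genotype[j] == a2:
                p += c
        return p

    def fitness(self, genotype: str, sites: list[int]) -> float:
        f = float(self.threshold_function(self.potential(genotype, sites)))
        for coeffs, cliff in self.extra_potentials:
            p = sum(coeffs.get((site, aa), 0.0) for site, aa in zip(sites, genotype))
            f *= float(cliff(p))
        return f


def assign_true_fitness(
    lib: SegmentLibrary, landscape: GroundTruthLandscape
) -> dict[str, float]:
    """True fitness for every amino-acid genotype present in the library.

    Every non-wildtype state occurring in the library must carry a
    coefficient (wildtype states default to 0); nonsense genotypes are
    forced to fitness 0.
    """
    wt = lib.wildtype_aa
    seen_states = set()
    for v in lib.nt_variants:
        if not v.is_nonsense:
            seen_states.update(zip(lib.sites, v.aa))
    all_coeffs = dict(landscape.coefficients)
    for coeffs, _ in landscape.extra_potentials:
        all_coeffs.update(coeffs)
    missing = [
        (site, aa)
        for site, aa in sorted(seen_states)
        if (site, aa) not in all_coeffs and aa != wt[lib.sites.index(site)]
    ]
    if missing:
        raise ValueError(f"missing landscape coefficients for states: {missing}")

    out: dict[str, float] = {}
    for v in lib.nt_variants:
        if v.aa in out:
            continue
        if STOP in v.aa:
            out[v.aa] = 0.0
        else:
            out[v.aa] = landscape.fitness(v.aa, lib.sites)
    return out


def random_landscape(
    lib: SegmentLibrary,
    rng: np.random.Generator,
    coeff_scale: float = 1.5,
    cliff: CliffFunction | None = None,
    extant_coeff_scale: float | None = None,
) -> GroundTruthLandscape:
    """Random unidimensional cliff landscape over the states of a library.

    Non-wildtype state penalties are drawn ~ |N(0, scale)| so that genotypes
    accumulating replacements drift towards and over the threshold.
    Non-extant byproduct states (absent from the design) get penalties on
    the same scale unless ``extant_coeff_scale`` distinguishes them.
    """
    cliff = cliff or CliffFunction()
    wt = lib.wildtype_aa
    states = set()
    for v in lib.nt_variants:
        if not v.is_nonsense:
            states.update(zip(lib.sites, v.aa))
    coeffs = {}
    for site, aa in sorted(states):
        if aa == wt[lib.sites.index(site)]:
            continue
        extant = aa in lib.states_per_site[site]
        scale = coeff_scale if (extant or extant_coeff_scale is None) else extant_coeff_scale
        coeffs[(site, aa)] = float(abs(rng.normal(0.0, scale)))
    return GroundTruthLandscape(coefficients=coeffs, threshold_function=cliff)
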