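"""Combinatorial segment libraries built from degenerate codons.

A segment library encodes, at each variable site, the set of amino-acid
states observed across orthologues ("extant" states, the first one being the
wildtype).  One IUPAC-degenerate codon per site covers all target states;
expanding the degenerate codons yields every nucleotide variant actually
synthesised, including synonymous redundancy, non-extant byproduct amino
acids and premature stop (nonsense) variants.  The two variable halves of a
segment are separated by a constant region, matching the two-block amplicon
design used for orientation, merging and template-switch detection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import yaml

from fitscape.codons import (
    STOP,
    expand_degenerate_codon,
    site_degenerate_codon,
    translate,
    translate_codon,
)


@dataclass(frozen=True)
class NtVariant:
    """One nucleotide variant of the library (variable codons + constant region)."""

    nt: str
    aa: str
    is_nonsense: bool
    is_extant_combination: bool


@dataclass
class SegmentLibrary:
    segment_id: str
    sites: list[int]
    states_per_site: dict[int, list[str]]  # first listed state = wildtype
    nt_variants: list[NtVariant]
    constant_region: str
    degenerate_codons: dict[int, str] = field(default_factory=dict)

    @property
    def wildtype_aa(self) -> str:
        return "".join(self.states_per_site[s][0] for s in self.sites)

    @property
    def n_left_sites(self) -> int:
        return (len(self.sites) + 1) // 2

    def split_halves(self, nt: str) -> tuple[str, str]:
        """Left variable half and right variable half of a nucleotide sequence."""
        cut = 3 * self.n_left_sites
        return nt[:cut], nt[cut + len(self.constant_region):]

    @property
    def combinatorial_count(self) -> int:
        """Size of the full combinatorial amino-acid set (product of multiplicities)."""
        return combinatorial_count([len(self.states_per_site[s]) for s in self.sites])

    def aa_of(self, nt: str) -> str:
        left, right = self.split_halves(nt)
        return translate(left + right)

    def translations(self) -> dict[str, str]:
        return {v.nt: v.aa for v in self.nt_variants}

    def extant_aa_genotypes(self) -> list[str]:
        """All amino-acid genotypes composed only of extant states."""
        return [
            "".join(combo)
            for combo in itertools.product(
                *(self.states_per_site[s] for s in self.sites)
            )
        ]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, v in enumerate(self.nt_variants):
                fh.write(f">{self.segment_id}_{i} aa={v.aa} nonsense={int(v.is_nonsense)}\n")
                fh.write(v.nt + "\n")


def combinatorial_count(multiplicities: list[int]) -> int:
    """Number of amino-acid genotypes in the full combinatorial set.

    E.g. per-site extant-state multiplicities (2,2,3,2,2,3,3,4,2,4,4)
    give 55,296 genotypes.
    """
    if any(m < 1 for m in multiplicities):
        raise ValueError("site multiplicity must be >= 1")
    return math.prod(multiplicities)


def build_library(
    states_per_site: dict[int, list[str]] | list[list[str]],
    wildtype_codons: dict[int, str] | None = None,
    constant_region: str = "GGTTCTGGT",
    segment_id: str = "segment",
    max_variants: int = 2_000_000,
) -> SegmentLibrary:
    """Build a segment library from per-site extant amino-acid states.

    Parameters
    ----------
    states_per_site
        For each site (1-based positions, or a plain list), the amino-acid
        states to cover; the first listed state is the wildtype.
    wildtype_codons
        Optional codon per site for the wildtype state; anchors the choice
        of representative codons for the other states.
    constant_region
        Invariant nucleotide sequence separating the two variable halves.
    max_variants
        Safety cap on the number of enumerated nucleotide variants.

    Returns
    -------
    SegmentLibrary with every nucleotide variant implied by the degenerate
    codons: synonymous codons, non-extant byproducts and nonsense variants.
    """
    if isinstance(states_per_site, list):
        states_per_site = {i + 1: list(v) for i, v in enumerate(states_per_site)}
    sites = sorted(states_per_site)
    if not sites:
        raise ValueError("library needs at least one site")
    wildtype_codons = wildtype_codons or {}

    degen: dict[int, str] = {}
    site_codons: dict[int, tuple[str, ...]] = {}
    for s in sites:
        degen[s] = site_degenerate_codon(
            list(states_per_site[s]), wildtype_codons.get(s)
        )
        site_codons[s] = expand_degenerate_codon(degen[s])

    n_variants = math.prod(len(site_codons[s]) for s in sites)
    if n_variants > max_variants:
        raise ValueError(
            f"{n_variants} nucleotide variants exceed max_variants={max_variants}"
        )

    extant_sets = {s: set(states_per_site[s]) for s in sites}
    n_left = (len(sites) + 1) // 2
    variants = []
    for combo in itertools.product(*(site_codons[s] for s in sites)):
        aa = "".join(translate_codon(c) for c in combo)
        nt = "".join(combo[:n_left]) + constant_region + "".join(combo[n_left:])
        is_nonsense = STOP in aa
        is_extant = not is_nonsense and all(
            a in extant_sets[s] for a, s in zip(aa, sites)
        )
        variants.append(NtVariant(nt, aa, is_nonsense, is_extant))

    return SegmentLibrary(
        segment_id=segment_id,
        sites=sites,
        states_per_site={s: list(states_per_site[s]) for s in sites},
        nt_variants=variants,
        constant_region=constant_region,
        degenerate_codons=degen,
    )


def build_library_from_yaml(path) -> SegmentLibrary:
    """Build a library from a YAML config.

    Expected keys: ``segment_id``, ``constant_region``, ``sites`` (mapping
    position -> list of states, first = wildtype) and optional
    ``wildtype_codons`` (mapping position -> codon).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return build_library(
        states_per_site={int(k): list(v) for k, v in cfg["sites"].items()},
        wildtype_codons={int(k): v for k, v in (cfg.get("wildtype_codons") or {}).items()},
        constant_region=cfg.get("constant_region", "GGTTCTGGT"),
        segment_id=str(cfg.get("segment_id", "segment")),
    )
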