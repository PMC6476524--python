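"""Genetic-code and degenerate-codon utilities.

The mutant libraries are synthesised with one IUPAC-degenerate codon per
variable site.  A degenerate codon that covers a set of target amino acids
also encodes byproduct codons: synonymous variants of the targets, non-target
("non-extant") amino acids and premature stop codons.  These helpers expand
degenerate codons, pick representative codons for target states and translate
variable regions.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

STOP = "*"

#: IUPAC degenerate nucleotide codes.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_TO_IUPAC = {frozenset(v): k for k, v in IUPAC.items()}

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = STOP

#: Codons per amino acid (sorted), including '*' for stops.
CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    CODONS_FOR_AA.setdefault(_aa, []).append(_codon)

AMINO_ACIDS = frozenset(a for a in CODONS_FOR_AA if a != STOP)


def translate_codon(codon: str) -> str:
    return CODON_TABLE[codon.upper()]


def translate(nt: str) -> str:
    """Translate a nucleotide sequence of whole codons ('*' for stops)."""
    if len(nt) % 3:
        raise ValueError(f"length {len(nt)} is not a multiple of 3")
    return "".join(translate_codon(nt[i : i + 3]) for i in range(0, len(nt), 3))


@lru_cache(maxsize=None)
def expand_degenerate_codon(codon: str) -> tuple[str, ...]:
    """All plain codons matched by an IUPAC-degenerate codon."""
    sets = [IUPAC[c] for c in codon.upper()]
    return tuple("".join(p) for p in itertools.product(*sets))


def degenerate_union(codons: list[str]) -> str:
    """The smallest IUPAC-degenerate codon containing all given codons.

    Formed position-wise, so it may match codons beyond the inputs — those
    are the library byproducts.
    """
    out = []
    for pos in range(3):
        out.append(_TO_IUPAC[frozenset(c[pos] for c in codons)])
    return "".join(out)


def representative_codon(aa: str, anchor: str | None = None) -> str:
    """Pick a codon for ``aa``, preferring agreement with an anchor codon.

    Maximises the number of positions shared with ``anchor`` (the wildtype
    codon of the site), breaking ties lexicographically.  This mirrors how
    degenerate libraries are designed to keep the byproduct set small.
    """
    options = CODONS_FOR_AA.get(aa)
    if not options:
        raise ValueError(f"unknown amino-acid letter {aa!r}")
    if anchor is None:
        return options[0]
    anchor = anchor.upper()
    # options are sorted, so max() resolves ties to the lexicographically
    # smallest codon.
    return max(options, key=lambda c: sum(a == b for a, b in zip(c, anchor)))


def site_degenerate_codon(states: list[str], wildtype_codon: str | None = None) -> str:
    """Degenerate codon covering the target amino-acid states of one site.

    The first state is the wildtype; its codon anchors the representative
    codons chosen for the other states.
    """
    if not states:
        raise ValueError("site with zero amino-acid states")
    for s in states:
        if s not in AMINO_ACIDS:
            raise ValueError(f"unknown amino-acid letter {s!r}")
    wt = states[0]
    if wildtype_codon is None:
        wildtype_codon = representative_codon(wt)
    elif translate_codon(wildtype_codon) != wt:
        raise ValueError(
            f"wildtype codon {wildtype_codon} does not encode {wt}"
        )
    reps = [wildtype_codon.upper()]
    for s in states[1:]:
        reps.append(representative_codon(s, anchor=wildtype_codon))
    return degenerate_union(reps)
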