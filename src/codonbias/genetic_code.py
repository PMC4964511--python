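"""Standard genetic code with synonymous-family and degeneracy structure.

Codon usage statistics (RSCU, ENC, CAI, GC3s) are all defined relative to
synonymous families — the sets of codons translated to the same amino acid.
This module derives that structure once from the standard (NCBI table 1)
genetic code and exposes it as an immutable object used everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

from Bio.Data import CodonTable

BASES = ("T", "C", "A", "G")


def to_rna(codon: str) -> str:
    """DNA codon -> RNA spelling (T->U), as printed in codon usage tables."""
    return codon.replace("T", "U")


def to_dna(codon: str) -> str:
    """RNA codon -> DNA spelling (U->T), the internal representation."""
    return codon.upper().replace("U", "T")


@dataclass(frozen=True)
class GeneticCode:
    """The codon -> amino-acid map plus the synonymous-family layout.

    Attributes
    ----------
    codon_to_aa:
        Map over the 61 sense codons (DNA alphabet) to one-letter amino
        acids.
    stop_codons:
        The three termination codons.
    families:
        Amino acid -> tuple of its codons, in TCAG order.
    """

    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset[str]
    families: Mapping[str, tuple[str, ...]] = field(repr=False)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """All 61 sense codons in TCAG order."""
        return tuple(sorted(self.codon_to_aa, key=_tcag_key))

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(self.families)

    def degeneracy(self, aa: str) -> int:
        """Family size (number of synonymous codons) of ``aa``."""
        return len(self.families[aa])

    @property
    def single_codon_aas(self) -> tuple[str, ...]:
        """Amino acids with exactly one codon (Met, Trp in the standard code)."""
        return tuple(a for a, f in self.families.items() if len(f) == 1)

    @property
    def synonymous_codons(self) -> tuple[str, ...]:
        """The 59 codons belonging to families of size >= 2.

        This is the codon set over which GC3s, RSCU-based correspondence
        analysis and optimal-codon calls are defined (stops and the
        single-codon amino acids Met/Trp carry no synonymous choice).
        """
        return tuple(
            c
            for c in self.sense_codons
            if len(self.families[self.codon_to_aa[c]]) > 1
        )

    def degeneracy_classes(self) -> dict[int, tuple[str, ...]]:
        """Amino acids grouped by family size (the 2/3/4/6-fold classes)."""
        out: dict[int, list[str]] = {}
        for aa, fam in self.families.items():
            if len(fam) > 1:
                out.setdefault(len(fam), []).append(aa)
        return {k: tuple(v) for k, v in sorted(out.items())}


def _tcag_key(codon: str) -> tuple[int, ...]:
    return tuple(BASES.index(b) for b in codon)


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (61 sense codons, 3 stops)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    codon_to_aa = dict(table.forward_table)
    fams: dict[str, list[str]] = {}
    for codon in sorted(codon_to_aa, key=_tcag_key):
        fams.setdefault(codon_to_aa[codon], []).append(codon)
    return GeneticCode(
        codon_to_aa=codon_to_aa,
        stop_codons=frozenset(table.stop_codons),
        families={a: tuple(c) for a, c in fams.items()},
    )
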