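"""The standard genetic code as the substrate for codon-usage statistics.

Everything downstream (RSCU, CAI, ENc, positional GC) is defined relative to
the partition of the 61 sense codons into synonymous families.  Under the
standard code that partition has 2 single-codon amino acids (Met, Trp),
9 two-fold, 1 three-fold (Ile), 5 four-fold and 3 six-fold families; the 59
codons belonging to degenerate families are the "informative" codons on
which synonymous-preference statistics are computed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

BASES = "TCAG"

#: All 64 codons in TCAG order (the conventional codon-table layout).
ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(BASES, BASES, BASES)
)


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino acid map plus the synonymous-family structure.

    Attributes
    ----------
    codon_to_aa
        Map over the 61 sense codons (DNA alphabet, e.g. ``"ATG" -> "M"``).
    families
        Amino acid -> tuple of its synonymous codons.
    stop_codons
        The three stop codons (TAA, TAG, TGA).
    single_codons
        Codons of the two non-degenerate amino acids (ATG, TGG).
    """

    codon_to_aa: dict[str, str]
    families: dict[str, tuple[str, ...]]
    stop_codons: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})
    single_codons: frozenset[str] = frozenset({"ATG", "TGG"})
    stop_family_key: str = field(default="*", repr=False)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if c not in self.stop_codons)

    @property
    def degenerate_families(self) -> dict[str, tuple[str, ...]]:
        """Sense families with two or more codons (18 families, 59 codons)."""
        return {aa: cs for aa, cs in self.families.items() if len(cs) > 1}

    @property
    def informative_codons(self) -> tuple[str, ...]:
        """The 59 sense codons belonging to degenerate families, TCAG order."""
        member = {c for cs in self.degenerate_families.values() for c in cs}
        return tuple(c for c in ALL_CODONS if c in member)

    def family_of(self, codon: str) -> tuple[str, ...]:
        """All synonymous codons of ``codon`` (including itself)."""
        if codon in self.stop_codons:
            return tuple(sorted(self.stop_codons))
        return self.families[self.codon_to_aa[codon]]

    def family_size_census(self) -> dict[int, int]:
        """Number of sense families of each size (degeneracy class census)."""
        census: dict[int, int] = {}
        for codons in self.families.values():
            census[len(codons)] = census.get(len(codons), 0) + 1
        return census

    def third_base(self, codon: str) -> str:
        return codon[2]


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (NCBI translation table 1)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    codon_to_aa = dict(table.forward_table)
    families: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = codon_to_aa.get(codon)
        if aa is not None:
            families.setdefault(aa, []).append(codon)
    return GeneticCode(
        codon_to_aa=codon_to_aa,
        families={aa: tuple(cs) for aa, cs in families.items()},
    )
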