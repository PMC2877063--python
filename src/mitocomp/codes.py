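"""Genetic-code logic for metazoan mitochondrial protein genes.

The invertebrate mitochondrial code (NCBI translation table 5) differs from
the standard code in ways that matter for insect mtDNA: TGA encodes Trp,
ATA encodes Met, and AGA/AGG encode Ser, leaving only TAA and TAG as stop
codons (62 sense codons).  Insect mitochondrial open reading frames also
start on a relaxed set of initiator codons (the ATN family plus GTG and the
unusual TCG seen in anopheline COI).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

#: All 64 codons in fixed lexicographic order over A<C<G<T.
ALL_CODONS = tuple("".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3))

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table with start/stop metadata.

    Attributes
    ----------
    table_id:
        NCBI translation table number (5 = invertebrate mitochondrial).
    codon_to_aa:
        64-entry map codon -> one-letter amino acid ('*' for stops).
    stop_codons:
        Codons terminating translation.
    allowed_start_codons:
        Codons accepted as initiators for protein-coding genes.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str]
    allowed_start_codons: frozenset[str]
    sense_codons: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        if len(self.codon_to_aa) != 64:
            raise ValueError("codon_to_aa must map all 64 codons")
        object.__setattr__(
            self,
            "sense_codons",
            tuple(c for c in ALL_CODONS if c not in self.stop_codons),
        )

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def aa(self, codon: str) -> str:
        """Translate one codon; any codon containing N yields 'X'."""
        if "N" in codon:
            return "X"
        return self.codon_to_aa[codon]

    def synonymous_families(self) -> dict[str, tuple[str, ...]]:
        """Map amino acid -> tuple of sense codons encoding it."""
        fam: dict[str, list[str]] = {}
        for c in self.sense_codons:
            fam.setdefault(self.codon_to_aa[c], []).append(c)
        return {aa: tuple(cs) for aa, cs in fam.items()}


def invertebrate_mito_code() -> GeneticCode:
    """NCBI table 5 with the anopheline start-codon repertoire (ATN, GTG, TCG)."""
    table = CodonTable.unambiguous_dna_by_id[5]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    starts = set(table.start_codons) | {"ATA", "ATC", "ATG", "ATT", "TCG", "GTG"}
    return GeneticCode(
        table_id=5,
        codon_to_aa=mapping,
        stop_codons=frozenset(table.stop_codons),
        allowed_start_codons=frozenset(starts),
    )


#: Module-level default code; immutable, safe to share.
MITO_CODE = invertebrate_mito_code()
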