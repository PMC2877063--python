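"""Base-composition, strand-asymmetry, sliding-window, control-region motif
and codon-usage statistics.

Strand asymmetry is summarised by the GC and AT skews,

    G-skew = (G - C) / (G + C),        T-skew = (T - A) / (T + A),

computed on the majority (H) strand as written.  Negative values indicate a
C- and A-rich majority strand, the usual state of insect mtDNA.  Reported
(printed) values truncate toward zero — 3 decimals for skews, 1 for
percentages — while full precision is retained on the objects themselves.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .codes import GeneticCode, MITO_CODE
from .genome import (
    FeatureTable,
    MitoGenome,
    ValidationError,
    extract_gene,
)


def truncate(x: float, decimals: int) -> float:
    """Truncate toward zero at the given number of decimals."""
    scale = 10**decimals
    return math.trunc(x * scale) / scale


@dataclass(frozen=True)
class CompositionProfile:
    """Base counts plus derived composition and skew statistics."""

    a: int
    c: int
    g: int
    t: int
    n: int = 0

    @classmethod
    def from_sequence(cls, seq: str) -> "CompositionProfile":
        if not seq:
            raise ValidationError("empty sequence")
        counts = Counter(seq.upper())
        bad = set(counts) - set("ACGTN")
        if bad:
            raise ValidationError(f"non-nucleotide symbols {sorted(bad)}")
        return cls(
            a=counts["A"], c=counts["C"], g=counts["G"], t=counts["T"], n=counts["N"]
        )

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t + self.n

    @property
    def acgt(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def at_percent(self) -> float:
        return 100.0 * (self.a + self.t) / self.acgt

    @property
    def gc_percent(self) -> float:
        return 100.0 * (self.g + self.c) / self.acgt

    @property
    def g_skew(self) -> float | None:
        """(G-C)/(G+C); None when the sequence has no G or C (undefined)."""
        gc = self.g + self.c
        return None if gc == 0 else (self.g - self.c) / gc

    @property
    def t_skew(self) -> float | None:
        """(T-A)/(T+A); None when the sequence has no A or T (undefined)."""
        at = self.a + self.t
        return None if at == 0 else (self.t - self.a) / at

    def reported(self) -> dict[str, float | None]:
        """Printed-precision values (truncation toward zero)."""
        return {
            "at_percent": truncate(self.at_percent, 1),
            "gc_percent": truncate(self.gc_percent, 1),
            "g_skew": None if self.g_skew is None else truncate(self.g_skew, 3),
            "t_skew": None if self.t_skew is None else truncate(self.t_skew, 3),
        }


def composition(seq: str) -> CompositionProfile:
    """Composition profile of a nucleotide sequence."""
    return CompositionProfile.from_sequence(seq)


def sliding_profile(
    genome: MitoGenome, window: int, step: int
) -> list[tuple[int, float, float]]:
    """(midpoint, AT%, GC%) over sliding windows; circular genomes wrap.

    For circular input the number of windows is ceil(length/step); for
    linear input windows stop at the last full window.
    """
    if window <= 0 or step <= 0:
        raise ValidationError("window and step must be positive")
    L = genome.length
    if window > L:
        raise ValidationError("window larger than genome")
    seq = genome.sequence
    out = []
    if genome.circular:
        n_windows = math.ceil(L / step)
        doubled = seq + seq
        for k in range(n_windows):
            start = k * step
            sub = doubled[start : start + window]
            prof = CompositionProfile.from_sequence(sub)
            mid = (start + window // 2) % L + 1
            out.append((mid, prof.at_percent, prof.gc_percent))
    else:
        for start in range(0, L - window + 1, step):
            sub = seq[start : start + window]
            prof = CompositionProfile.from_sequence(sub)
            out.append((start + window // 2 + 1, prof.at_percent, prof.gc_percent))
    return out


def poly_t_stretch(cr_seq: str, min_len: int = 5) -> tuple[int, int] | None:
    """Longest poly-T run of at least ``min_len`` nt; leftmost on ties.

    Returns (1-based position, length) or None.  The T-stretch of the
    control region is implicated in transcription regulation and is a
    conserved dipteran motif.
    """
    if min_len < 2:
        raise ValidationError("min_len must be >= 2")
    best: tuple[int, int] | None = None
    seq = cr_seq.upper()
    i = 0
    while i < len(seq):
        if seq[i] == "T":
            j = i
            while j < len(seq) and seq[j] == "T":
                j += 1
            run = j - i
            if run >= min_len and (best is None or run > best[1]):
                best = (i + 1, run)
            i = j
        else:
            i += 1
    return best


@dataclass(frozen=True)
class CodonUsageTable:
    """Codon counts aggregated over protein-coding genes, with RSCU."""

    counts: dict[str, int]
    code: GeneticCode = field(default=MITO_CODE, repr=False)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    @property
    def total_nonstop(self) -> int:
        return self.total_codons - sum(
            self.counts.get(s, 0) for s in self.code.stop_codons
        )

    @property
    def rscu(self) -> dict[str, float | None]:
        return rscu(self, self.code)


def codon_usage(
    genome: MitoGenome, table: FeatureTable, code: GeneticCode = MITO_CODE
) -> CodonUsageTable:
    """Codon counts over the 13 protein-coding genes on their coding strands.

    Complete terminal stop codons are counted (they appear in published
    usage tables) but excluded from the non-stop total; incomplete
    (polyadenylation-completed) stops are excluded entirely; codons
    containing N are skipped.  Overlapping genes are counted independently.
    """
    counts: Counter[str] = Counter()
    for f in table.pcgs:
        cds = extract_gene(genome, f)
        if f.incomplete_stop:
            trailing = len(f.stop_codon or "")
            if (len(cds) - trailing) % 3 != 0:
                raise ValidationError(f"{f.name}: frameshifted coding sequence")
            cds = cds[: len(cds) - trailing]  # drop the partial stop
        elif len(cds) % 3 != 0:
            raise ValidationError(f"{f.name}: frameshifted coding sequence")
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if "N" in codon:
                continue
            counts[codon] += 1
    return CodonUsageTable(counts=dict(counts), code=code)


def rscu(usage: CodonUsageTable, code: GeneticCode = MITO_CODE) -> dict[str, float | None]:
    """Relative synonymous codon usage: count / mean count in the family.

    Stop codons are excluded from families.  A family never observed has no
    defined RSCU; its codons map to None rather than a fabricated 0.
    """
    values: dict[str, float | None] = {}
    for aa, family in code.synonymous_families().items():
        total = sum(usage.counts.get(c, 0) for c in family)
        if total == 0:
            for c in family:
                values[c] = None
        else:
            mean = total / len(family)
            for c in family:
                values[c] = usage.counts.get(c, 0) / mean
    return values
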