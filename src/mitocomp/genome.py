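"""Mitogenome sequences, gene feature tables, and gene extraction/translation.

Coordinates are 1-based inclusive throughout, matching GenBank convention.
The "H" strand is the strand as written in the FASTA record (the
majority-gene strand); "L"-strand genes are read as the reverse complement
of their coordinate slice.  Origin-spanning features are rejected: the
insect mitogenomes this package targets annotate none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codes import GeneticCode, MITO_CODE, revcomp

VALID_BASES = set("ACGTN")


class FormatError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input parsed but violates a domain invariant."""


class FeatureKind(str, Enum):
    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CONTROL = "control"


@dataclass(frozen=True)
class MitoGenome:
    """A (usually circular) mitochondrial genome sequence."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"{self.id}: non-nucleotide symbols {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature: protein gene, tRNA, rRNA, or control region."""

    name: str
    kind: FeatureKind
    strand: str  # "H" or "L"; control region carries "H" by convention
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None  # TAA/TAG complete; TA/T incomplete

    def __post_init__(self):
        if self.strand not in ("H", "L"):
            raise ValidationError(f"{self.name}: unknown strand {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"{self.name}: invalid coordinates {self.start}-{self.end}"
            )
        if self.kind is FeatureKind.PCG:
            if not self.start_codon or not self.stop_codon:
                raise ValidationError(
                    f"{self.name}: protein gene needs start and stop codons"
                )

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def incomplete_stop(self) -> bool:
        return self.stop_codon in ("TA", "T")


@dataclass(frozen=True)
class FeatureTable:
    """Ordered gene annotation for one genome (the shape of a GenBank gene table)."""

    genome_id: str
    features: tuple[GeneFeature, ...]

    def __post_init__(self):
        feats = tuple(sorted(self.features, key=lambda f: (f.start, f.end)))
        object.__setattr__(self, "features", feats)
        counts = {k: 0 for k in FeatureKind}
        for f in feats:
            counts[f.kind] += 1
        if counts[FeatureKind.CONTROL] > 1:
            raise ValidationError("more than one control region")
        if counts[FeatureKind.PCG] > 13:
            raise ValidationError("more than 13 protein-coding genes")
        if counts[FeatureKind.TRNA] > 22:
            raise ValidationError("more than 22 tRNA genes")
        if counts[FeatureKind.RRNA] > 2:
            raise ValidationError("more than 2 rRNA genes")

    def __iter__(self):
        return iter(self.features)

    def __len__(self):
        return len(self.features)

    def by_kind(self, kind: FeatureKind) -> tuple[GeneFeature, ...]:
        return tuple(f for f in self.features if f.kind is kind)

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def pcgs(self) -> tuple[GeneFeature, ...]:
        return self.by_kind(FeatureKind.PCG)

    @property
    def control_region(self) -> GeneFeature | None:
        cr = self.by_kind(FeatureKind.CONTROL)
        return cr[0] if cr else None


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[MitoGenome]:
    """Read nucleotide FASTA records as genomes (upper-cased, U -> T)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    genomes = []
    for rec in records:
        seq = str(rec.seq).upper().replace("U", "T")
        genomes.append(MitoGenome(id=rec.id, sequence=seq))
    return genomes


def write_fasta(genomes: list[MitoGenome], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Feature tables (tab-separated, mirroring the published gene-table layout)

_HEADER = ["Gene", "Kind", "Strand", "Position", "Anticodon", "Size", "Start codon", "Stop codon"]


def write_feature_table(
    table: FeatureTable, path: str | Path, provenance: str = ""
) -> None:
    lines = [provenance.rstrip("\n")] if provenance else []
    lines.append("\t".join(_HEADER))
    for f in table.features:
        lines.append(
            "\t".join(
                [
                    f.name,
                    f.kind.value,
                    f.strand,
                    f"{f.start}-{f.end}",
                    f.anticodon or "",
                    str(f.size),
                    f.start_codon or "",
                    f.stop_codon or "",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_feature_table(path: str | Path, genome_id: str = "") -> FeatureTable:
    """Parse a tab-separated feature table.

    Columns: Gene, Kind, Strand, Position ("start-end"), Anticodon, Size,
    Start codon, Stop codon.  The Kind column may be omitted, in which case
    it is inferred from the gene name.  The Size column, when present and
    non-empty, is checked against the coordinate arithmetic.
    """
    text = Path(path).read_text()
    rows = [
        line.rstrip("\n").split("\t")
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if not rows:
        raise FormatError(f"{path}: empty feature table")
    header = [h.strip() for h in rows[0]]
    has_kind = "Kind" in header
    idx = {name: header.index(name) for name in header}
    problems: list[str] = []
    feats: list[GeneFeature] = []
    seen_spans: dict[str, tuple[int, int]] = {}
    for lineno, row in enumerate(rows[1:], start=2):

        def col(name, default=""):
            i = idx.get(name)
            if i is None or i >= len(row):
                return default
            return row[i].strip()

        name = col("Gene")
        strand = col("Strand") or "H"
        pos = col("Position")
        try:
            start_s, end_s = pos.split("-")
            start, end = int(start_s), int(end_s)
        except ValueError:
            problems.append(f"line {lineno} ({name}): bad position {pos!r}")
            continue
        kind_s = col("Kind") if has_kind else _infer_kind(name)
        try:
            kind = FeatureKind(kind_s)
        except ValueError:
            problems.append(f"line {lineno} ({name}): unknown kind {kind_s!r}")
            continue
        if name in seen_spans and seen_spans[name] == (start, end):
            problems.append(f"line {lineno}: duplicate feature {name!r}")
            continue
        seen_spans[name] = (start, end)
        size_s = col("Size")
        if size_s and int(size_s) != end - start + 1:
            problems.append(
                f"line {lineno} ({name}): stated size {size_s} != {end - start + 1}"
            )
            continue
        try:
            feats.append(
                GeneFeature(
                    name=name,
                    kind=kind,
                    strand=strand,
                    start=start,
                    end=end,
                    anticodon=col("Anticodon") or None,
                    start_codon=col("Start codon") or None,
                    stop_codon=col("Stop codon") or None,
                )
            )
        except ValidationError as exc:
            problems.append(f"line {lineno}: {exc}")
    if problems:
        raise ValidationError("; ".join(problems))
    return FeatureTable(genome_id=genome_id or Path(path).stem, features=tuple(feats))


def _infer_kind(name: str) -> str:
    low = name.lower()
    if low.startswith("trna"):
        return "tRNA"
    if "rrna" in low or low in ("12s", "16s"):
        return "rRNA"
    if "control" in low or low in ("cr", "at-rich", "d-loop"):
        return "control"
    return "PCG"


# ---------------------------------------------------------------------------
# Gene extraction and translation


def extract_gene(genome: MitoGenome, feature: GeneFeature) -> str:
    """Coding-strand sequence of a feature (revcomp for L-strand genes)."""
    if feature.end > genome.length:
        raise ValidationError(
            f"{feature.name}: end {feature.end} beyond genome length {genome.length}"
        )
    segment = genome.sequence[feature.start - 1 : feature.end]
    return revcomp(segment) if feature.strand == "L" else segment


@dataclass(frozen=True)
class Translation:
    protein: str
    internal_stops: tuple[int, ...]  # 0-based codon indices
    padded: bool

    @property
    def has_internal_stops(self) -> bool:
        return bool(self.internal_stops)


def translate_pcg(
    cds: str, code: GeneticCode = MITO_CODE, incomplete_stop: bool = False
) -> Translation:
    """Translate a mitochondrial protein gene.

    A 1- or 2-nt trailing remainder is accepted only with ``incomplete_stop``
    and is padded with A, the residue added by post-transcriptional
    polyadenylation; the resulting (or literal) terminal stop is not part of
    the protein.  Internal stops are reported, not raised: a diverged or
    mis-framed gene is a data problem for the caller to judge.
    """
    cds = cds.upper()
    remainder = len(cds) % 3
    padded = False
    if remainder:
        if not incomplete_stop:
            raise ValidationError(
                f"CDS length {len(cds)} not a multiple of 3 and incomplete_stop unset"
            )
        cds = cds + "A" * (3 - remainder)
        padded = True
    aas = []
    stops: list[int] = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if code.is_stop(codon):
            if i == n_codons - 1:
                break  # terminal stop, not translated
            stops.append(i)
            aas.append("*")
        else:
            aas.append(code.aa(codon))
    else:
        # no terminal stop codon; fine for genes annotated without one
        pass
    if stops:
        warnings.warn(f"internal stop codon(s) at codon index {stops}", stacklevel=2)
    return Translation(protein="".join(aas), internal_stops=tuple(stops), padded=padded)


def detect_overlaps(table: FeatureTable) -> list[tuple[str, str, int]]:
    """All pairs of features whose coordinate ranges intersect, with overlap size."""
    out = []
    feats = table.features
    for i, a in enumerate(feats):
        for b in feats[i + 1 :]:
            if b.start > a.end:
                break  # sorted by start
            ov = min(a.end, b.end) - b.start + 1
            if ov > 0:
                out.append((a.name, b.name, ov))
    return out
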