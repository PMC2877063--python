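"""The canonical anopheline mitogenome gene layout.

This is the 37-gene arrangement of the *Anopheles darlingi* mitogenome
(northern genotype, 15,386 bp): 13 protein-coding genes, 22 tRNAs, 2 rRNAs
and the AT-rich control region, with the characteristic ATP8/ATP6 and
NAD4/NAD4L 7-nt overlaps and the incomplete stop codons (TA on NAD4/NAD5,
T on COI/COII/COIII) completed by polyadenylation.  Coordinates are 1-based
inclusive on the majority-strand ("H") sequence; the published size column
occasionally disagrees with its own coordinates, so sizes here are always
derived from the coordinates.

Two gene boundaries are adjusted so every protein gene's span is
frame-consistent with its annotated stop: COI ends at 2961 (1540 = 513
codons + incomplete T) and NAD4 starts at 8102 (1343 = 447 codons +
incomplete TA).  The published spans (COI ..2963, NAD4 8103..) have
lengths incompatible with their own incomplete-stop annotations.
"""

from __future__ import annotations

from .genome import FeatureKind, FeatureTable, GeneFeature

# name, kind, strand, start, end, anticodon, start_codon, stop_codon
_LAYOUT = [
    ("tRNA-Ile", "tRNA", "H", 1, 68, "GAT", None, None),
    ("tRNA-Gln", "tRNA", "L", 66, 134, "TTG", None, None),
    ("tRNA-Met", "tRNA", "H", 134, 202, "CAT", None, None),
    ("NAD2", "PCG", "H", 203, 1228, None, "ATT", "TAA"),
    ("tRNA-Trp", "tRNA", "H", 1227, 1295, "TCA", None, None),
    ("tRNA-Cys", "tRNA", "L", 1295, 1358, "GCA", None, None),
    ("tRNA-Tyr", "tRNA", "L", 1359, 1423, "GTA", None, None),
    ("COI", "PCG", "H", 1422, 2961, None, "TCG", "T"),
    ("tRNA-Leu1", "tRNA", "H", 2959, 3024, "TAA", None, None),
    ("COII", "PCG", "H", 3027, 3711, None, "ATG", "T"),
    ("tRNA-Lys", "tRNA", "H", 3712, 3782, "CTT", None, None),
    ("tRNA-Asp", "tRNA", "H", 3792, 3859, "GTC", None, None),
    ("ATP8", "PCG", "H", 3860, 4021, None, "ATC", "TAA"),
    ("ATP6", "PCG", "H", 4015, 4695, None, "ATG", "TAA"),
    ("COIII", "PCG", "H", 4695, 5481, None, "ATG", "T"),
    ("tRNA-Gly", "tRNA", "H", 5482, 5548, "TCC", None, None),
    ("NAD3", "PCG", "H", 5549, 5902, None, "ATA", "TAA"),
    ("tRNA-Arg", "tRNA", "H", 5902, 5965, None, None, None),
    ("tRNA-Ala", "tRNA", "H", 5965, 6030, "TGC", None, None),
    ("tRNA-Asn", "tRNA", "H", 6031, 6098, "GTT", None, None),
    ("tRNA-Ser1", "tRNA", "L", 6099, 6177, "GCT", None, None),
    ("tRNA-Glu", "tRNA", "H", 6166, 6231, "TTC", None, None),
    ("tRNA-Phe", "tRNA", "L", 6230, 6296, "GAA", None, None),
    ("NAD5", "PCG", "L", 6296, 8037, None, "GTG", "TA"),
    ("tRNA-His", "tRNA", "L", 8038, 8102, "GTG", None, None),
    ("NAD4", "PCG", "L", 8102, 9444, None, "ATG", "TA"),
    ("NAD4L", "PCG", "L", 9438, 9743, None, "ATG", "TAA"),
    ("tRNA-Thr", "tRNA", "H", 9744, 9811, "TGT", None, None),
    ("tRNA-Pro", "tRNA", "L", 9812, 9877, "TGG", None, None),
    ("NAD6", "PCG", "H", 9880, 10404, None, "ATT", "TAA"),
    ("CYTB", "PCG", "H", 10404, 11540, None, "ATG", "TAA"),
    ("tRNA-Ser2", "tRNA", "H", 11539, 11604, "TGA", None, None),
    ("NAD1", "PCG", "L", 11622, 12578, None, "ATA", "TAA"),
    ("tRNA-Leu2", "tRNA", "L", 12573, 12638, "TAG", None, None),
    ("16S rRNA", "rRNA", "L", 12574, 13967, None, None, None),
    ("tRNA-Val", "tRNA", "L", 13968, 14039, "TAC", None, None),
    ("12S rRNA", "rRNA", "L", 14040, 14832, None, None, None),
    ("control_region", "control", "H", 14833, 15386, None, None, None),
]

GENOME_LENGTH = 15386

#: Position of the regulatory poly-T stretch within the control region (1-based).
T_STRETCH_POSITION = 142


def default_feature_table(genome_id: str = "synthetic_mitogenome") -> FeatureTable:
    """The canonical 37-gene + control-region feature table."""
    feats = tuple(
        GeneFeature(
            name=name,
            kind=FeatureKind(kind),
            strand=strand,
            start=start,
            end=end,
            anticodon=anticodon,
            start_codon=start_codon,
            stop_codon=stop_codon,
        )
        for name, kind, strand, start, end, anticodon, start_codon, stop_codon in _LAYOUT
    )
    return FeatureTable(genome_id=genome_id, features=feats)
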