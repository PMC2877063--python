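"""Pairwise divergence: global alignment, percent identity, control-region
variation counting, Nei–Gojobori (NG86) dN/dS, and the empirical arthropod
mtDNA rate ("2.3% per million years") age conversion.

The aligner is a Needleman–Wunsch/Gotoh global aligner with affine gap
costs: a gap of length k costs ``gap_open + (k-1)*gap_extend``.  Traceback
ties are broken deterministically — diagonal (match/mismatch) first, then a
gap in the first sequence, then a gap in the second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .codes import GeneticCode, MITO_CODE
from .genome import ValidationError

NEG = -1e30


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences (gaps as '-')."""

    seq_a: str
    seq_b: str
    score: float

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValidationError("aligned rows differ in length")
        for x, y in zip(self.seq_a, self.seq_b):
            if x == "-" and y == "-":
                raise ValidationError("column gapped in both rows")

    @property
    def columns(self) -> int:
        return len(self.seq_a)


def global_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Optimal global alignment under an affine gap scheme (Gotoh).

    Dynamic programming rows are vectorised with numpy; the within-row
    (horizontal-gap) recurrence is folded into a running-maximum scan so the
    whole table fills in O(n) numpy passes.
    """
    if not a or not b:
        raise ValidationError("cannot align empty sequences")
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    barr = np.frombuffer(b.encode(), dtype="S1")
    # State matrices: M diag, X gap-in-b (consumes a), Y gap-in-a (consumes b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    j = np.arange(1, m + 1)
    Y[0, 1:] = gap_open + (j - 1) * gap_extend
    i_idx = np.arange(1, n + 1)
    X[1:, 0] = gap_open + (i_idx - 1) * gap_extend
    ge_j = gap_extend * np.arange(m + 1)
    for i in range(1, n + 1):
        sub = np.where(barr == a[i - 1].encode(), match, mismatch)
        best_prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = best_prev[:-1] + sub
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) + gap_open,
            X[i - 1, 1:] + gap_extend,
        )
        # Y[i, j] = max_k<j ( max(M,X)[i,k] + gap_open + (j-1-k)*gap_extend )
        base = np.maximum(M[i], X[i]) + gap_open - ge_j
        running = np.maximum.accumulate(base[:-1])
        Y[i, 1:] = np.maximum(Y[i, 1:], running + ge_j[:-1])
        Y[i, 0] = NEG

    # Traceback; tie order: M (diagonal), Y (gap in a), X (gap in b).
    eps = 1e-9
    i, jj = n, m
    finals = [("M", M[n, m]), ("Y", Y[n, m]), ("X", X[n, m])]
    score = max(v for _, v in finals)
    state = next(s for s, v in finals if v >= score - eps)
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or jj > 0:
        if state == "M":
            ra.append(a[i - 1])
            rb.append(b[jj - 1])
            sub = match if a[i - 1] == b[jj - 1] else mismatch
            target = M[i, jj] - sub
            i, jj = i - 1, jj - 1
            for s, v in (("M", M[i, jj]), ("Y", Y[i, jj]), ("X", X[i, jj])):
                if abs(v - target) <= eps:
                    state = s
                    break
        elif state == "Y":  # gap in a, consumes b
            ra.append("-")
            rb.append(b[jj - 1])
            prev = jj - 1
            if abs(M[i, prev] + gap_open - Y[i, jj]) <= eps:
                state = "M"
            elif abs(Y[i, prev] + gap_extend - Y[i, jj]) <= eps:
                state = "Y"
            else:
                state = "X"
            jj = prev
        else:  # X: gap in b, consumes a
            ra.append(a[i - 1])
            rb.append("-")
            prev = i - 1
            if abs(M[prev, jj] + gap_open - X[i, jj]) <= eps:
                state = "M"
            elif abs(Y[prev, jj] + gap_open - X[i, jj]) <= eps:
                state = "Y"
            else:
                state = "X"
            i = prev
        if i == 0 and state == "M" and jj > 0:
            state = "Y"
        if jj == 0 and state == "M" and i > 0:
            state = "X"
    return PairwiseAlignment(
        seq_a="".join(reversed(ra)), seq_b="".join(reversed(rb)), score=float(score)
    )


def _trim_terminal_gaps(aln: PairwiseAlignment) -> tuple[str, str]:
    a, b = aln.seq_a, aln.seq_b
    start, end = 0, len(a)
    while start < end and (a[start] == "-" or b[start] == "-"):
        start += 1
    while end > start and (a[end - 1] == "-" or b[end - 1] == "-"):
        end -= 1
    return a[start:end], b[start:end]


def percent_identity(aln: PairwiseAlignment, reported: bool = False) -> float:
    """100 x matched columns / columns; internal gap columns count in the
    denominator, terminal overhang gaps do not.  ``reported`` truncates to
    one decimal, the printed precision of identity tables."""
    a, b = _trim_terminal_gaps(aln)
    if not a:
        raise ValidationError("alignment has no columns after trimming")
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    value = 100.0 * matches / len(a)
    return math.trunc(value * 10) / 10 if reported else value


def count_variation(aln: PairwiseAlignment) -> tuple[int, int, int]:
    """(variable_sites, substitutions, indel_events).

    A maximal run of contiguous gap columns in one row is one indel event
    contributing one variable site, so variable_sites == substitutions +
    indel_events.
    """
    subs = 0
    indels = 0
    prev_gap_row = 0  # 0 none, 1 gap in a, 2 gap in b
    for x, y in zip(aln.seq_a, aln.seq_b):
        if x == "-" or y == "-":
            row = 1 if x == "-" else 2
            if row != prev_gap_row:
                indels += 1
            prev_gap_row = row
        else:
            prev_gap_row = 0
            if x != y:
                subs += 1
    return subs + indels, subs, indels


# ---------------------------------------------------------------------------
# Nei–Gojobori (1986) pairwise dN/dS


@dataclass(frozen=True)
class DnDsResult:
    """Pairwise synonymous/nonsynonymous substitution summary."""

    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float | None
    dS: float | None
    omega: float | None
    codons: int

    @property
    def omega_defined(self) -> bool:
        return self.omega is not None


def _syn_fraction(codon: str, code: GeneticCode) -> float:
    """Fractional count of synonymous sites in one codon (0..3).

    Each position contributes (synonymous one-step changes)/3; a change
    into a stop codon counts as nonsynonymous, so per-codon site counts
    always total 3.
    """
    aa = code.codon_to_aa[codon]
    s = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if not code.is_stop(alt) and code.codon_to_aa[alt] == aa:
                s += 1.0 / 3.0
    return s


def _pathway_counts(c1: str, c2: str, code: GeneticCode) -> tuple[float, float]:
    """Average (syn, nonsyn) observed differences over minimal pathways.

    Pathways through stop codons are excluded; if every ordering is blocked
    the average falls back to all orderings with stop-passing steps counted
    as nonsynonymous.
    """
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    d = len(diff_pos)
    if d == 0:
        return 0.0, 0.0
    if d == 1:
        p = diff_pos[0]
        alt = c2
        syn = (
            not code.is_stop(c1)
            and not code.is_stop(alt)
            and code.codon_to_aa[c1] == code.codon_to_aa[alt]
        )
        return (1.0, 0.0) if syn else (0.0, 1.0)

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        cur = c1
        syn = nonsyn = 0.0
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if code.is_stop(nxt) and nxt != c2 and not allow_stops:
                return None
            if (
                not code.is_stop(cur)
                and not code.is_stop(nxt)
                and code.codon_to_aa[cur] == code.codon_to_aa[nxt]
            ):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        return syn, nonsyn

    results = [r for r in (walk(o, False) for o in permutations(diff_pos)) if r]
    if not results:
        results = [walk(o, True) for o in permutations(diff_pos)]
    syn = sum(r[0] for r in results) / len(results)
    nonsyn = sum(r[1] for r in results) / len(results)
    return syn, nonsyn


def _jukes_cantor(p: float) -> float | None:
    """d = -(3/4) ln(1 - 4p/3); undefined (None) at p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_dnds(cds_a: str, cds_b: str, code: GeneticCode = MITO_CODE) -> DnDsResult:
    """Nei–Gojobori pairwise dN/dS with pathway averaging and JC correction.

    Sequences must be equal-length, in frame, and gap-free; codons
    containing N (in either sequence) are skipped.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValidationError("sequences differ in length")
    if len(cds_a) % 3 != 0:
        raise ValidationError("length not a multiple of 3")
    if "-" in cds_a or "-" in cds_b:
        raise ValidationError("gapped input; provide ungapped in-frame CDS")
    S = N = Sd = Nd = 0.0
    ncod = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if "N" in ca or "N" in cb:
            continue
        ncod += 1
        S += (_syn_fraction(ca, code) + _syn_fraction(cb, code)) / 2.0
        sd, nd = _pathway_counts(ca, cb, code)
        Sd += sd
        Nd += nd
    if ncod == 0:
        raise ValidationError("no comparable codons")
    N = 3.0 * ncod - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    omega = None
    if dS is not None and dS > 0 and dN is not None:
        omega = dN / dS
    return DnDsResult(
        N=N, S=S, Nd=Nd, Sd=Sd, pN=pN, pS=pS, dN=dN, dS=dS, omega=omega, codons=ncod
    )


#: Empirical arthropod mtDNA pairwise divergence rate, percent per My.
BROWER_RATE_PCT_PER_MY = 2.3


def brower_age(p_distance_percent: float) -> float:
    """Age (My) from percent divergence at the standard arthropod mtDNA rate."""
    if p_distance_percent < 0:
        raise ValidationError("distance must be non-negative")
    return p_distance_percent / BROWER_RATE_PCT_PER_MY
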