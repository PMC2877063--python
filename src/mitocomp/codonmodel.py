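"""Goldman–Yang (GY94) codon substitution model and pruning likelihood.

The model acts on the 62 sense codons of the invertebrate mitochondrial
code.  The instantaneous rate from codon i to j is nonzero only for single
nucleotide changes:

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

scaled so the expected number of substitutions per codon per unit branch
length is 1 at the given omega.  The chain is reversible, so transition
probabilities come from a symmetrised eigendecomposition and the
likelihood is invariant to root placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .codes import GeneticCode, MITO_CODE
from .genome import ValidationError
from .trees import PhyloTree, TreeArrays, tree_to_arrays

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free in-frame codon matrix for one gene or a concatenation.

    ``matrix`` holds sense-codon indices (into ``code.sense_codons``),
    shape (n_taxa, n_codons).
    """

    taxa: tuple[str, ...]
    matrix: np.ndarray
    code: GeneticCode = field(default=MITO_CODE, repr=False)

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise ValidationError("matrix shape does not match taxa")

    @property
    def n_codons(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @classmethod
    def from_sequences(
        cls,
        sequences: dict[str, str],
        code: GeneticCode = MITO_CODE,
        drop_incomplete: bool = True,
    ) -> "CodonAlignment":
        """Build from equal-length nucleotide strings.

        Columns (codon sites) containing a gap, an N, or a stop codon in
        any taxon are removed when ``drop_incomplete`` (the count is
        recoverable by comparing n_codons with the input length).
        """
        taxa = tuple(sequences)
        seqs = [sequences[t].upper() for t in taxa]
        L = len(seqs[0])
        if any(len(s) != L for s in seqs):
            raise ValidationError("sequences differ in length")
        usable = L - (L % 3)
        codon_index = {c: i for i, c in enumerate(code.sense_codons)}
        cols = []
        for site in range(usable // 3):
            codons = [s[3 * site : 3 * site + 3] for s in seqs]
            if any(c not in codon_index for c in codons):
                if drop_incomplete:
                    continue
                raise ValidationError(f"unusable codon at site {site}")
            cols.append([codon_index[c] for c in codons])
        if not cols:
            raise ValidationError("no usable codon sites")
        return cls(taxa=taxa, matrix=np.array(cols, dtype=np.int16).T, code=code)

    def codon_strings(self, taxon: str) -> str:
        row = self.matrix[self.taxa.index(taxon)]
        return "".join(self.code.sense_codons[i] for i in row)


def f3x4_frequencies(aln: CodonAlignment, pseudocount: float = 0.5) -> np.ndarray:
    """F3x4 codon frequencies: per-codon-position nucleotide frequencies
    multiplied and renormalised over sense codons.

    A small pseudocount keeps every sense codon reachable when a position
    class lacks one of the four nucleotides.
    """
    code = aln.code
    sense = code.sense_codons
    nt_index = {n: i for i, n in enumerate("ACGT")}
    pos_counts = np.full((3, 4), pseudocount)
    for row in aln.matrix:
        for idx in row:
            codon = sense[idx]
            for pos in range(3):
                pos_counts[pos, nt_index[codon[pos]]] += 1
    pos_freqs = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    freqs = np.array(
        [
            pos_freqs[0, nt_index[c[0]]]
            * pos_freqs[1, nt_index[c[1]]]
            * pos_freqs[2, nt_index[c[2]]]
            for c in sense
        ]
    )
    return freqs / freqs.sum()


def _pair_structure(code: GeneticCode):
    """Cache the single-step change structure over sense codons."""
    sense = code.sense_codons
    n = len(sense)
    single = np.zeros((n, n), dtype=bool)
    is_ts = np.zeros((n, n), dtype=bool)
    is_nonsyn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(sense):
        for j, cj in enumerate(sense):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            is_ts[i, j] = diffs[0] in _TRANSITIONS
            is_nonsyn[i, j] = code.codon_to_aa[ci] != code.codon_to_aa[cj]
    return single, is_ts, is_nonsyn


_STRUCT_CACHE: dict[int, tuple] = {}


def _structure(code: GeneticCode):
    key = id(code)
    if key not in _STRUCT_CACHE:
        _STRUCT_CACHE[key] = _pair_structure(code)
    return _STRUCT_CACHE[key]


def gy94_matrix(
    freqs: np.ndarray,
    kappa: float,
    omega: float,
    code: GeneticCode = MITO_CODE,
) -> np.ndarray:
    """Scaled GY94 instantaneous rate matrix over sense codons."""
    if kappa <= 0 or omega < 0:
        raise ValidationError("kappa must be > 0 and omega >= 0")
    single, is_ts, is_nonsyn = _structure(code)
    Q = np.where(single, freqs[None, :], 0.0)
    Q = Q * np.where(is_ts, kappa, 1.0) * np.where(is_nonsyn, omega, 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(freqs * np.diag(Q)).sum()
    if rate <= 0:
        raise ValidationError("degenerate rate matrix (omega=0 with no synonymous paths?)")
    return Q / rate


@dataclass
class ReversibleEigen:
    """Eigendecomposition of a reversible rate matrix for fast P(t)."""

    freqs: np.ndarray
    eigvals: np.ndarray
    left: np.ndarray  # D^{-1/2} U
    right: np.ndarray  # U^T D^{1/2}

    @classmethod
    def from_q(cls, Q: np.ndarray, freqs: np.ndarray) -> "ReversibleEigen":
        d = np.sqrt(freqs)
        S = (Q * d[:, None]) / d[None, :]
        S = (S + S.T) / 2.0  # enforce exact symmetry
        vals, U = np.linalg.eigh(S)
        return cls(freqs=freqs, eigvals=vals, left=U / d[:, None] * 1.0, right=(U * d[:, None]).T)

    def transition(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValidationError("negative branch length")
        P = (self.left * np.exp(self.eigvals * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


class CodonLikelihood:
    """Felsenstein pruning for codon data on a fixed tree.

    Patterns are compressed once; branch lengths are indexed by the node
    below each branch in :class:`~mitocomp.trees.TreeArrays` order.
    """

    def __init__(self, aln: CodonAlignment, tree: PhyloTree):
        self.aln = aln
        self.code = aln.code
        self.arrays: TreeArrays = tree_to_arrays(tree)
        missing = set(self.arrays.tip_labels) - set(aln.taxa)
        if missing:
            raise ValidationError(f"taxa missing from alignment: {sorted(missing)}")
        order = [aln.taxa.index(t) for t in self.arrays.tip_labels]
        mat = aln.matrix[order]
        patterns, weights = np.unique(mat, axis=1, return_counts=True)
        self.patterns = patterns  # (n_tips, n_patterns)
        self.weights = weights.astype(float)
        self.n_states = len(self.code.sense_codons)
        self._children = [self.arrays.children(i) for i in range(self.arrays.n_nodes)]

    @property
    def n_branches(self) -> int:
        return self.arrays.n_nodes - 1

    def default_blen(self) -> np.ndarray:
        return self.arrays.blen[:-1].copy()

    def pattern_loglik(self, Ps: list[np.ndarray], freqs: np.ndarray) -> np.ndarray:
        """Per-pattern log-likelihood given per-branch transition matrices."""
        arr = self.arrays
        npat = self.patterns.shape[1]
        logscale = np.zeros(npat)
        partial: list[np.ndarray | None] = [None] * arr.n_nodes
        for tip in range(arr.n_tips):
            states = self.patterns[tip]
            partial[tip] = Ps[tip].T[states]  # message to parent: (npat, nstates)
        for node in range(arr.n_tips, arr.n_nodes):
            L = np.ones((npat, self.n_states))
            for child in self._children[node]:
                msg = partial[child]
                if child >= arr.n_tips:
                    msg = msg @ Ps[child].T
                L *= msg
            scale = L.max(axis=1)
            scale[scale == 0] = 1.0
            L /= scale[:, None]
            logscale += np.log(scale)
            partial[node] = L
        root = partial[arr.root]
        lik = root @ freqs
        return np.log(lik) + logscale

    def _transition_set(
        self, kappa: float, omega: float, freqs: np.ndarray, blen: np.ndarray
    ) -> list[np.ndarray]:
        eig = ReversibleEigen.from_q(gy94_matrix(freqs, kappa, omega, self.code), freqs)
        return [eig.transition(t) for t in blen] + [None]  # root has no branch

    def loglik_single(
        self, kappa: float, omega: float, freqs: np.ndarray, blen: np.ndarray
    ) -> float:
        Ps = self._transition_set(kappa, omega, freqs, blen)
        return float(self.weights @ self.pattern_loglik(Ps, freqs))

    def pattern_loglik_mixture(
        self,
        kappa: float,
        classes: list[tuple[float, float]],
        freqs: np.ndarray,
        blen: np.ndarray,
    ) -> np.ndarray:
        """Per-pattern log of sum_k p_k * Pr(pattern | omega_k)."""
        props = np.array([p for p, _ in classes])
        if np.any(props < -1e-12) or abs(props.sum() - 1.0) > 1e-8:
            raise ValidationError("class proportions must be a distribution")
        logliks = []
        for p_k, omega_k in classes:
            Ps = self._transition_set(kappa, omega_k, freqs, blen)
            logliks.append(self.pattern_loglik(Ps, freqs))
        stack = np.stack(logliks)  # (K, npat)
        with np.errstate(divide="ignore"):
            logp = np.log(np.maximum(props, 1e-300))
        return logsumexp(stack + logp[:, None], axis=0)

    def loglik_mixture(
        self,
        kappa: float,
        classes: list[tuple[float, float]],
        freqs: np.ndarray,
        blen: np.ndarray,
    ) -> float:
        per_pat = self.pattern_loglik_mixture(kappa, classes, freqs, blen)
        total = float(self.weights @ per_pat)
        if not np.isfinite(total):
            bad = int(np.argmax(~np.isfinite(per_pat)))
            raise ValidationError(f"non-finite likelihood at pattern {bad}")
        return total

    def loglik_branchwise(
        self,
        kappa: float,
        omega_by_branch: np.ndarray,
        freqs: np.ndarray,
        blen: np.ndarray,
    ) -> float:
        """Single-class likelihood with a per-branch omega (branch models)."""
        eigs: dict[float, ReversibleEigen] = {}
        Ps: list[np.ndarray | None] = []
        for i in range(self.n_branches):
            w = float(omega_by_branch[i])
            if w not in eigs:
                eigs[w] = ReversibleEigen.from_q(
                    gy94_matrix(freqs, kappa, w, self.code), freqs
                )
            Ps.append(eigs[w].transition(blen[i]))
        Ps.append(None)
        return float(self.weights @ self.pattern_loglik(Ps, freqs))


def site_class_lnL(
    aln: CodonAlignment,
    tree: PhyloTree,
    kappa: float,
    freqs: np.ndarray,
    classes: list[tuple[float, float]],
    blen: np.ndarray | None = None,
) -> float:
    """Log-likelihood of a site-class (random-sites) codon model."""
    lik = CodonLikelihood(aln, tree)
    if blen is None:
        blen = lik.default_blen()
    return lik.loglik_mixture(kappa, classes, freqs, blen)
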