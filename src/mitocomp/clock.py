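"""Calibrated Bayesian divergence-time estimation on a fixed rooted topology.

The model follows the standard relaxed-clock setup for species-level
mtDNA dating: a fixed rooted topology with unknown node ages (My), a
strict or uncorrelated-lognormal (UCLN) clock mapping ages to expected
substitutions (branch length = rate x duration), a GTR+Gamma(+I)
substitution model, a pure-birth (Yule) prior on node ages, and normal
calibration priors on selected clades.  Co-estimating the topology is out
of scope: the topology is an input, the main simplification relative to a
full BEAST analysis.

Sampling is Metropolis-within-Gibbs: uniform-window moves on internal
node ages (respecting parent/child order), multiplicative scale moves on
rates and hyperparameters.  A "generation" is one elementary proposal, so
chain lengths are comparable to conventional MCMC samplers' generation
counts.

Under the Yule process conditioned on the root age and the number of
tips, the joint density of the remaining node ages is proportional to
exp(-lambda * total tree duration); that is the form used here, which also
makes prior-only sampling directly checkable against forward simulation
of the pure-birth process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .genome import ValidationError
from .simulate import GTRParams, discrete_gamma_rates, gtr_q
from .codonmodel import ReversibleEigen
from .trees import PhyloTree, TreeArrays, tree_to_arrays

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# GTR+Gamma(+I) likelihood


class NucLikelihood:
    """Felsenstein pruning for nucleotide data with discrete-gamma rates."""

    def __init__(self, alignment: dict[str, str], arrays: TreeArrays):
        self.arrays = arrays
        missing = set(arrays.tip_labels) - set(alignment)
        if missing:
            raise ValidationError(f"taxa missing from alignment: {sorted(missing)}")
        L = len(next(iter(alignment.values())))
        if any(len(alignment[t]) != L for t in arrays.tip_labels):
            raise ValidationError("alignment rows differ in length")
        mat = np.array(
            [[_NT_INDEX.get(c, -1) for c in alignment[t]] for t in arrays.tip_labels],
            dtype=np.int16,
        )
        if (mat < 0).any():
            raise ValidationError("non-ACGT symbol in alignment")
        patterns, weights = np.unique(mat, axis=1, return_counts=True)
        self.patterns = patterns
        self.weights = weights.astype(float)
        self._children = [arrays.children(i) for i in range(arrays.n_nodes)]
        self._constant = np.all(patterns == patterns[0:1, :], axis=0)

    def loglik(self, params: GTRParams, blen: np.ndarray) -> float:
        """Total log-likelihood for branch lengths in substitutions/site."""
        f = np.asarray(params.freqs)
        eig = ReversibleEigen.from_q(gtr_q(params), f)
        if params.gamma_shape is None:
            cat_rates = np.array([1.0])
        else:
            cat_rates = discrete_gamma_rates(
                params.gamma_shape, params.gamma_categories
            )
        pinv = params.p_invariant
        k = len(cat_rates)
        per_cat = np.empty((k, self.patterns.shape[1]))
        for ci, r in enumerate(cat_rates):
            Ps = [eig.transition(t * r) for t in blen[: self.arrays.n_nodes - 1]]
            Ps.append(None)
            per_cat[ci] = self._pattern_loglik(Ps, f)
        # mix gamma categories (equal weight) and the invariant class
        m = per_cat.max(axis=0)
        mixed = np.log(np.exp(per_cat - m).sum(axis=0) / k) + m
        if pinv > 0:
            lik_var = (1.0 - pinv) * np.exp(mixed)
            lik_inv = np.where(
                self._constant, pinv * f[self.patterns[0]], 0.0
            )
            total = np.log(lik_var + lik_inv)
        else:
            total = mixed
        out = float(self.weights @ total)
        if not np.isfinite(out):
            bad = int(np.argmax(~np.isfinite(total)))
            raise ValidationError(f"non-finite likelihood at site pattern {bad}")
        return out

    def _pattern_loglik(self, Ps, freqs) -> np.ndarray:
        arr = self.arrays
        npat = self.patterns.shape[1]
        logscale = np.zeros(npat)
        partial: list[np.ndarray | None] = [None] * arr.n_nodes
        for tip in range(arr.n_tips):
            partial[tip] = Ps[tip].T[self.patterns[tip]]
        for node in range(arr.n_tips, arr.n_nodes):
            Lk = np.ones((npat, 4))
            for child in self._children[node]:
                msg = partial[child]
                if child >= arr.n_tips:
                    msg = msg @ Ps[child].T
                Lk *= msg
            scale = Lk.max(axis=1)
            scale[scale == 0] = 1.0
            Lk /= scale[:, None]
            logscale += np.log(scale)
            partial[node] = Lk
        return np.log(partial[arr.root] @ freqs) + logscale


def gtr_gamma_lnL(
    alignment: dict[str, str], tree: PhyloTree, params: GTRParams
) -> float:
    """GTR+Gamma(+I) log-likelihood of an alignment on a tree whose branch
    lengths are in substitutions/site."""
    arrays = tree_to_arrays(tree)
    return NucLikelihood(alignment, arrays).loglik(params, arrays.blen)


# ---------------------------------------------------------------------------
# Clock models, calibrations, MCMC


@dataclass(frozen=True)
class ClockModel:
    """Strict or uncorrelated-lognormal clock.

    ``rate_prior_mean``/``rate_prior_sd`` give the normal prior on the mean
    substitution rate (units: substitutions/site per My — the time unit of
    the input ages).  ``ucld_stdev_prior_mean`` is the mean of the
    exponential prior on the lognormal spread parameter.
    """

    kind: str = "UCLN"  # "strict" or "UCLN"
    rate_prior_mean: float = 0.1
    rate_prior_sd: float = 0.05
    ucld_stdev_prior_mean: float = 0.33

    def __post_init__(self):
        if self.kind not in ("strict", "UCLN"):
            raise ValidationError("clock kind must be 'strict' or 'UCLN'")
        if not (
            math.isfinite(self.rate_prior_mean) and math.isfinite(self.rate_prior_sd)
        ):
            raise ValidationError("rate prior parameters must be finite")


@dataclass(frozen=True)
class Calibration:
    """Normal prior on the age of the MRCA of ``taxa``."""

    taxa: tuple[str, ...]
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0 or self.mean <= 0:
            raise ValidationError("calibration mean and sd must be positive")

    @classmethod
    def of(cls, taxa, mean, sd=None):
        return cls(taxa=tuple(taxa), mean=mean, sd=sd if sd is not None else 0.05 * mean)


@dataclass
class McmcTrace:
    """Thinned posterior samples with chain metadata."""

    samples: pd.DataFrame  # indexed by generation
    generations: int
    thinning: int
    burn_in: float = 0.0
    age_columns: tuple[str, ...] = ()

    def post_burn_in(self, burn_in: float | None = None) -> pd.DataFrame:
        frac = self.burn_in if burn_in is None else burn_in
        cut = int(len(self.samples) * frac)
        return self.samples.iloc[cut:]


@dataclass(frozen=True)
class NodeAgeSummary:
    """Posterior summaries per node plus parameter ESS values."""

    mean_age: dict[str, float]
    hpd95: dict[str, tuple[float, float]]
    ess: dict[str, float]
    degenerate: tuple[str, ...] = ()


def mrca_index(arrays: TreeArrays, taxa: tuple[str, ...]) -> int:
    """Index of the most recent common ancestor of a set of tips."""
    tip_idx = []
    for t in taxa:
        if t not in arrays.tip_labels:
            raise ValidationError(f"unknown taxon {t!r}")
        tip_idx.append(arrays.tip_labels.index(t))
    tipsets: list[set[int]] = [set() for _ in range(arrays.n_nodes)]
    for i in range(arrays.n_tips):
        tipsets[i] = {i}
    for node in arrays.postorder:
        tipsets[arrays.parent[node]] |= tipsets[node]
    target = set(tip_idx)
    best = arrays.root
    for node in range(arrays.n_nodes):
        if target <= tipsets[node] and len(tipsets[node]) < len(tipsets[best]):
            best = node
    return best


def _node_ages_from_durations(arrays: TreeArrays) -> np.ndarray:
    """Node ages implied by branch durations (tips at age 0)."""
    ages = np.zeros(arrays.n_nodes)
    for node in arrays.postorder:
        parent = arrays.parent[node]
        ages[parent] = max(ages[parent], ages[node] + arrays.blen[node])
    return ages


def yule_log_prior(ages: np.ndarray, arrays: TreeArrays, birth_rate: float) -> float:
    """log p(ages | root age, n) under pure birth: -lambda * total duration."""
    total = 0.0
    for node in range(arrays.n_nodes - 1):
        total += ages[arrays.parent[node]] - ages[node]
    n_int = arrays.n_nodes - arrays.n_tips
    return (n_int - 1) * math.log(birth_rate) - birth_rate * total


@dataclass
class _State:
    ages: np.ndarray
    rates: np.ndarray  # per-branch (UCLN) or length-1 (strict)
    mean_rate: float
    ucld_stdev: float


def run_mcmc(
    alignment: dict[str, str] | None,
    tree: PhyloTree,
    clock: ClockModel,
    calibrations: list[Calibration],
    *,
    subst_model: GTRParams = GTRParams(),
    generations: int = 200_000,
    thinning: int = 100,
    seed: int = 0,
    birth_rate: float = 0.05,
    init_ages: np.ndarray | None = None,
) -> McmcTrace:
    """Sample node ages and clock parameters on a fixed rooted topology.

    ``alignment`` may be None for prior-only sampling.  ``tree`` must be
    rooted; its branch lengths, when present, are treated as durations and
    used to initialise node ages.  At least one calibration is required —
    without one the time scale is unidentifiable and the run is refused.
    """
    if not calibrations:
        raise ValidationError("at least one age calibration is required")
    arrays = tree_to_arrays(tree)
    n_tips, n_nodes = arrays.n_tips, arrays.n_nodes
    internal = list(range(n_tips, n_nodes))
    cal_nodes = []
    for cal in calibrations:
        node = mrca_index(arrays, cal.taxa)
        if node < n_tips:
            raise ValidationError(f"calibration on a tip: {cal.taxa}")
        cal_nodes.append((node, cal))

    lik = NucLikelihood(alignment, arrays) if alignment is not None else None
    rng = np.random.default_rng(seed)

    # --- initial state
    if init_ages is not None:
        ages = init_ages.copy()
    else:
        ages = _node_ages_from_durations(arrays)
        if ages[arrays.root] <= 0:
            root0 = max(c.mean for _, c in cal_nodes)
            depth = np.zeros(n_nodes)  # node depth from root (hops)
            for node in arrays.postorder[::-1]:
                depth[node] = depth[arrays.parent[node]] + 1
            maxd = depth[:n_tips].max()
            for i in internal:
                ages[i] = root0 * (1.0 - depth[i] / (maxd + 1))
            ages[arrays.root] = root0
        # nudge calibrated nodes toward their prior means where legal
    ages[:n_tips] = 0.0
    n_branch = n_nodes - 1
    rates = (
        np.array([clock.rate_prior_mean])
        if clock.kind == "strict"
        else np.full(n_branch, clock.rate_prior_mean)
    )
    state = _State(
        ages=ages,
        rates=rates,
        mean_rate=clock.rate_prior_mean,
        ucld_stdev=max(clock.ucld_stdev_prior_mean, 1e-3),
    )

    children = [arrays.children(i) for i in range(n_nodes)]

    def branch_lengths(st: _State) -> np.ndarray:
        dur = st.ages[arrays.parent[np.arange(n_branch)]] - st.ages[np.arange(n_branch)]
        r = st.rates if clock.kind == "UCLN" else st.rates[0]
        return dur * r

    def log_prior(st: _State) -> float:
        lp = yule_log_prior(st.ages, arrays, birth_rate)
        for node, cal in cal_nodes:
            lp += -0.5 * ((st.ages[node] - cal.mean) / cal.sd) ** 2 - math.log(cal.sd)
        lp += (
            -0.5 * ((st.mean_rate - clock.rate_prior_mean) / clock.rate_prior_sd) ** 2
        )
        if st.mean_rate <= 0:
            return -np.inf
        if clock.kind == "UCLN":
            s = st.ucld_stdev
            if s <= 0:
                return -np.inf
            mu = math.log(st.mean_rate) - 0.5 * s * s
            logr = np.log(st.rates)
            lp += float(
                np.sum(-0.5 * ((logr - mu) / s) ** 2 - logr - math.log(s))
            )
            lp += -s / clock.ucld_stdev_prior_mean  # exponential prior
        return lp

    def log_lik(st: _State) -> float:
        if lik is None:
            return 0.0
        bl = branch_lengths(st)
        if np.any(bl < 0):
            return -np.inf
        try:
            return lik.loglik(subst_model, bl)
        except ValidationError:
            return -np.inf

    cur_prior = log_prior(state)
    cur_lik = log_lik(state)
    if not np.isfinite(cur_prior + cur_lik):
        raise ValidationError("initial state has zero posterior density")

    moves: list[str] = ["age"] * len(internal) + ["mean_rate"]
    if clock.kind == "UCLN":
        moves += ["branch_rate"] * max(1, n_branch // 2) + ["ucld_stdev"]

    records = []
    age_cols = [f"age_{_node_name(arrays, i)}" for i in internal]

    def snapshot(gen):
        row = {"generation": gen}
        for col, i in zip(age_cols, internal):
            row[col] = state.ages[i]
        row["mean_rate"] = state.mean_rate
        if clock.kind == "UCLN":
            row["ucld_stdev"] = state.ucld_stdev
            row["rate_mean_realised"] = float(np.mean(state.rates))
        row["log_prior"] = cur_prior
        row["log_likelihood"] = cur_lik
        records.append(row)

    snapshot(0)
    for gen in range(1, generations + 1):
        kind = moves[rng.integers(len(moves))]
        if kind == "age":
            node = internal[rng.integers(len(internal))]
            lower = max(state.ages[c] for c in children[node])
            if node == arrays.root:
                # scale move on the root height above its oldest child
                old = state.ages[node]
                factor = math.exp(0.2 * (rng.random() - 0.5))
                new = lower + (old - lower) * factor
                log_hastings = math.log(factor)
            else:
                upper = state.ages[arrays.parent[node]]
                if upper <= lower:
                    continue
                new = lower + rng.random() * (upper - lower)
                log_hastings = 0.0
            old_age = state.ages[node]
            state.ages[node] = new
            new_prior = log_prior(state)
            new_lik = log_lik(state)
            if _accept(rng, new_prior + new_lik - cur_prior - cur_lik + log_hastings):
                cur_prior, cur_lik = new_prior, new_lik
            else:
                state.ages[node] = old_age
        elif kind == "mean_rate":
            old = state.mean_rate
            factor = math.exp(0.3 * (rng.random() - 0.5))
            state.mean_rate = old * factor
            if clock.kind == "strict":
                state.rates[:] = state.mean_rate
            new_prior = log_prior(state)
            new_lik = log_lik(state) if clock.kind == "strict" else cur_lik
            if _accept(
                rng, new_prior + new_lik - cur_prior - cur_lik + math.log(factor)
            ):
                cur_prior, cur_lik = new_prior, new_lik
            else:
                state.mean_rate = old
                if clock.kind == "strict":
                    state.rates[:] = old
        elif kind == "branch_rate":
            b = rng.integers(n_branch)
            old = state.rates[b]
            factor = math.exp(0.5 * (rng.random() - 0.5))
            state.rates[b] = old * factor
            new_prior = log_prior(state)
            new_lik = log_lik(state)
            if _accept(
                rng, new_prior + new_lik - cur_prior - cur_lik + math.log(factor)
            ):
                cur_prior, cur_lik = new_prior, new_lik
            else:
                state.rates[b] = old
        else:  # ucld_stdev
            old = state.ucld_stdev
            factor = math.exp(0.3 * (rng.random() - 0.5))
            state.ucld_stdev = old * factor
            new_prior = log_prior(state)
            if _accept(rng, new_prior - cur_prior + math.log(factor)):
                cur_prior = new_prior
            else:
                state.ucld_stdev = old
        if gen % thinning == 0:
            snapshot(gen)

    df = pd.DataFrame.from_records(records).set_index("generation")
    return McmcTrace(
        samples=df,
        generations=generations,
        thinning=thinning,
        age_columns=tuple(age_cols),
    )


def _accept(rng: np.random.Generator, log_ratio: float) -> bool:
    if log_ratio >= 0:
        return True
    return rng.random() < math.exp(max(log_ratio, -700.0))


def _node_name(arrays: TreeArrays, node: int) -> str:
    label = arrays.node_labels[node]
    if label:
        return label
    return f"node{node}"


def combine_traces(traces: list[McmcTrace], burn_in: float = 0.25) -> McmcTrace:
    """Concatenate post-burn-in samples of independent runs."""
    if not traces:
        raise ValidationError("no traces to combine")
    cols = list(traces[0].samples.columns)
    for t in traces[1:]:
        if list(t.samples.columns) != cols:
            raise ValidationError("trace parameter schemas differ")
    parts = [t.post_burn_in(burn_in).reset_index(drop=True) for t in traces]
    df = pd.concat(parts, ignore_index=True)
    df.index.name = "generation"
    return McmcTrace(
        samples=df,
        generations=sum(t.generations for t in traces),
        thinning=traces[0].thinning,
        burn_in=0.0,
        age_columns=traces[0].age_columns,
    )


def effective_sample_size(x: np.ndarray) -> float:
    """Autocorrelation-time ESS of one chain (bulk ESS)."""
    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        return float("nan")
    return float(az.ess(x))


def hpd_interval(x: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the samples."""
    lo, hi = az.hdi(np.asarray(x, dtype=float), hdi_prob=mass)
    return float(lo), float(hi)


def summarize(trace: McmcTrace, burn_in: float = 0.25) -> NodeAgeSummary:
    """Posterior mean, 95% HPD and ESS for every sampled parameter."""
    df = trace.post_burn_in(burn_in)
    if len(df) < 100:
        raise ValidationError("need at least 100 post-burn-in samples")
    mean_age: dict[str, float] = {}
    hpd: dict[str, tuple[float, float]] = {}
    ess: dict[str, float] = {}
    degenerate = []
    for col in df.columns:
        if col in ("log_prior", "log_likelihood"):
            continue
        x = df[col].to_numpy()
        m = float(np.mean(x))
        if np.std(x) == 0:
            hpd_lo = hpd_hi = m
            e = float("nan")
            degenerate.append(col)
        else:
            hpd_lo, hpd_hi = hpd_interval(x)
            e = effective_sample_size(x)
        if col.startswith("age_"):
            mean_age[col[4:]] = m
            hpd[col[4:]] = (hpd_lo, hpd_hi)
        ess[col] = e
    return NodeAgeSummary(
        mean_age=mean_age, hpd95=hpd, ess=ess, degenerate=tuple(degenerate)
    )


# ---------------------------------------------------------------------------
# Codon-position partitioning (SRD06-style 1st+2nd vs 3rd split)


def partition_alignment(
    alignment: dict[str, str], frame_start: int = 0
) -> dict[str, np.ndarray]:
    """Site-index sets for the (1st+2nd) and 3rd codon positions.

    The alignment must be a concatenation of in-frame protein-coding
    sequence; ``frame_start`` gives the 0-based column of the first codon
    position.
    """
    L = len(next(iter(alignment.values())))
    if (L - frame_start) % 3 != 0:
        raise ValidationError("alignment length incompatible with codon frame")
    sites = np.arange(frame_start, L)
    phase = (sites - frame_start) % 3
    return {
        "pos12": sites[phase != 2],
        "pos3": sites[phase == 2],
    }


def fit_rate_multiplier(
    alignment: dict[str, str],
    tree: PhyloTree,
    params: GTRParams,
    sites: np.ndarray | None = None,
) -> float:
    """ML scalar multiplier on all branch lengths for a site subset.

    Used to compare evolutionary rates between codon-position partitions
    sharing one tree.
    """
    from scipy.optimize import minimize_scalar

    if sites is not None:
        alignment = {t: "".join(s[i] for i in sites) for t, s in alignment.items()}
    arrays = tree_to_arrays(tree)
    lik = NucLikelihood(alignment, arrays)
    blen = arrays.blen.copy()

    def neg(logc):
        try:
            return -lik.loglik(params, blen * math.exp(logc))
        except ValidationError:
            return 1e12

    res = minimize_scalar(neg, bounds=(-6, 6), method="bounded")
    return float(math.exp(res.x))
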