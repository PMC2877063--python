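"""Maximum-likelihood codon site models (M0, M1a, M2a, M7, M8), the
branch model, and likelihood-ratio tests for positive selection.

All models share the GY94 substitution process; they differ in how the
selection parameter omega (dN/dS) is distributed across codon sites:

* M0 — one omega for all sites.
* M1a (nearly neutral) — classes (p0, omega0 in [0,1]) and (p1, omega1=1).
* M2a (selection) — M1a plus a class with omega2 >= 1.
* M7 — omega ~ Beta(p, q), discretised into K equal-probability classes.
* M8 — M7 plus a class with omega_s >= 1.
* branch — one omega per branch partition (foreground vs background).

Branch lengths and kappa are estimated under M0 and then held fixed for
the site models by default, mirroring the usual CODEML protocol of seeding
the richer models with M0 branch lengths; joint estimation is available
via ``fix_blen=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import betainc, betaincinv, expit, logit

from .codonmodel import CodonAlignment, CodonLikelihood, f3x4_frequencies
from .genome import ValidationError
from .trees import PhyloTree

SITE_MODELS = ("M0", "M1a", "M2a", "M7", "M8")

#: Count of omega-distribution parameters per model (kappa and branch
#: lengths are shared between null and alternative, so they cancel in df).
MODEL_N_PARAMS = {"M0": 1, "M1a": 2, "M2a": 4, "M7": 2, "M8": 4, "branch": 2}

_NESTED_PAIRS = {
    ("M1a", "M2a"),
    ("M7", "M8"),
    ("M0", "M2a"),
    ("M0", "M8"),
    ("M0", "branch"),
}

_BETA_BOUND = (5e-3, 99.0)


@dataclass
class SiteModelFit:
    """A fitted codon model: parameters, class structure and likelihood."""

    model: str
    lnL: float
    kappa: float
    omega_classes: list[tuple[float, float]]
    n_params: int
    branch_lengths: np.ndarray
    freqs: np.ndarray = field(repr=False, default=None)
    beta_p: float | None = None
    beta_q: float | None = None
    omega_pos: float | None = None
    converged: bool = True
    foreground_unidentifiable: bool = False

    @property
    def omega(self) -> float:
        """Single-ratio omega (meaningful for M0/branch foreground)."""
        return self.omega_classes[0][1]


@dataclass(frozen=True)
class LRTResult:
    lnL_null: float
    lnL_alt: float
    statistic: float
    df: int
    p_value: float


def discretize_beta(p: float, q: float, k: int = 10) -> list[tuple[float, float]]:
    """K equal-probability classes of Beta(p, q), each at its conditional mean."""
    edges = betaincinv(p, q, np.linspace(0.0, 1.0, k + 1))
    upper = betainc(p + 1.0, q, edges[1:])
    lower = betainc(p + 1.0, q, edges[:-1])
    means = (p / (p + q)) * (upper - lower) * k
    means = np.clip(means, 0.0, 1.0)
    return [(1.0 / k, float(m)) for m in means]


def _jitter(x: np.ndarray, rng: np.random.Generator, scale: float = 0.5) -> np.ndarray:
    return x + rng.normal(0.0, scale, size=len(x))


def _minimize(fun, x0, maxiter):
    return optimize.minimize(
        fun,
        x0,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-7},
    )


def _safe(fun):
    def wrapped(x):
        try:
            val = fun(x)
        except (ValidationError, FloatingPointError, np.linalg.LinAlgError):
            return 1e12
        if not np.isfinite(val):
            return 1e12
        return val

    return wrapped


def fit_m0(
    aln: CodonAlignment,
    tree: PhyloTree,
    freqs: np.ndarray | None = None,
    n_starts: int = 3,
    seed: int = 0,
    maxiter: int = 500,
) -> SiteModelFit:
    """Fit M0 (single omega) with joint branch-length estimation."""
    if freqs is None:
        freqs = f3x4_frequencies(aln)
    lik = CodonLikelihood(aln, tree)
    nb = lik.n_branches
    t0 = lik.default_blen()
    t0[t0 <= 0] = 0.05

    def neg(x):
        kappa = np.exp(x[0])
        omega = np.exp(x[1])
        blen = np.exp(x[2:])
        return -lik.loglik_single(kappa, omega, freqs, blen)

    neg = _safe(neg)
    x0 = np.concatenate([[np.log(2.0), np.log(0.2)], np.log(t0)])
    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(1, n_starts)):
        xs = x0 if s == 0 else _jitter(x0, rng)
        res = _minimize(neg, xs, maxiter)
        if best is None or res.fun < best.fun:
            best = res
    kappa = float(np.exp(best.x[0]))
    omega = float(np.exp(best.x[1]))
    blen = np.exp(best.x[2:])
    return SiteModelFit(
        model="M0",
        lnL=-float(best.fun),
        kappa=kappa,
        omega_classes=[(1.0, omega)],
        n_params=MODEL_N_PARAMS["M0"],
        branch_lengths=blen,
        freqs=freqs,
        converged=bool(best.success),
    )


def _model_spec(model: str, k_beta: int):
    """Return (n_free, x0, decode) for a site model's omega distribution."""
    if model == "M1a":
        x0 = np.array([logit(0.8), logit(0.1)])

        def decode(x):
            p0 = float(expit(x[0]))
            w0 = float(expit(x[1]))
            return [(p0, w0), (1.0 - p0, 1.0)], {}

    elif model == "M2a":
        x0 = np.array([logit(0.7), logit(0.8), logit(0.1), np.log(1.0)])

        def decode(x):
            p0 = float(expit(x[0]))
            p1 = float((1.0 - p0) * expit(x[1]))
            p2 = 1.0 - p0 - p1
            w0 = float(expit(x[2]))
            w2 = 1.0 + float(np.exp(x[3]))
            return [(p0, w0), (p1, 1.0), (p2, w2)], {"omega_pos": w2}

    elif model == "M7":
        x0 = np.array([np.log(0.5), np.log(2.0)])

        def decode(x):
            p = float(np.clip(np.exp(x[0]), *_BETA_BOUND))
            q = float(np.clip(np.exp(x[1]), *_BETA_BOUND))
            return discretize_beta(p, q, k_beta), {"beta_p": p, "beta_q": q}

    elif model == "M8":
        x0 = np.array([logit(0.9), np.log(0.5), np.log(2.0), np.log(1.0)])

        def decode(x):
            p0 = float(expit(x[0]))
            p = float(np.clip(np.exp(x[1]), *_BETA_BOUND))
            q = float(np.clip(np.exp(x[2]), *_BETA_BOUND))
            ws = 1.0 + float(np.exp(x[3]))
            classes = [(p0 * pr, w) for pr, w in discretize_beta(p, q, k_beta)]
            classes.append((1.0 - p0, ws))
            return classes, {"beta_p": p, "beta_q": q, "omega_pos": ws}

    else:
        raise ValidationError(f"unknown site model {model!r}")
    return len(x0), x0, decode


def fit_site_model(
    aln: CodonAlignment,
    tree: PhyloTree,
    model: str,
    m0: SiteModelFit | None = None,
    fix_blen: bool = True,
    k_beta: int = 10,
    n_starts: int = 3,
    seed: int = 0,
    maxiter: int = 500,
) -> SiteModelFit:
    """Fit one of M0/M1a/M2a/M7/M8 by bounded quasi-Newton with restarts."""
    if model == "M0":
        return fit_m0(aln, tree, n_starts=n_starts, seed=seed, maxiter=maxiter)
    if model not in SITE_MODELS:
        raise ValidationError(f"unknown site model {model!r}")
    if m0 is None:
        m0 = fit_m0(aln, tree, n_starts=1, seed=seed, maxiter=maxiter)
    freqs = m0.freqs
    lik = CodonLikelihood(aln, tree)
    blen0 = m0.branch_lengths
    nb = lik.n_branches
    n_free, x0_model, decode = _model_spec(model, k_beta)
    x0 = np.concatenate([[np.log(m0.kappa)], x0_model])
    if not fix_blen:
        x0 = np.concatenate([x0, np.log(np.maximum(blen0, 1e-4))])

    def neg(x):
        kappa = np.exp(x[0])
        classes, _ = decode(x[1 : 1 + n_free])
        blen = blen0 if fix_blen else np.exp(x[1 + n_free :])
        return -lik.loglik_mixture(kappa, classes, freqs, blen)

    neg = _safe(neg)
    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(1, n_starts)):
        xs = x0 if s == 0 else _jitter(x0, rng)
        res = _minimize(neg, xs, maxiter)
        if best is None or res.fun < best.fun:
            best = res
    classes, extras = decode(best.x[1 : 1 + n_free])
    blen = blen0 if fix_blen else np.exp(best.x[1 + n_free :])
    return SiteModelFit(
        model=model,
        lnL=-float(best.fun),
        kappa=float(np.exp(best.x[0])),
        omega_classes=classes,
        n_params=MODEL_N_PARAMS[model],
        branch_lengths=np.asarray(blen),
        freqs=freqs,
        converged=bool(best.success),
        **extras,
    )


def _branch_mask(lik: CodonLikelihood, tree: PhyloTree, labels: set[str]) -> np.ndarray:
    """Boolean mask over branches whose child node carries one of ``labels``."""
    arr = lik.arrays
    mask = np.zeros(lik.n_branches, dtype=bool)
    for i in range(lik.n_branches):
        lab = arr.tip_labels[i] if i < arr.n_tips else arr.node_labels[i]
        if lab is not None and lab in labels:
            mask[i] = True
    return mask


def fit_branch_model(
    aln: CodonAlignment,
    tree: PhyloTree,
    foreground_branches: list[str] | None = None,
    background_omega: float | None = 1.0,
    m0: SiteModelFit | None = None,
    seed: int = 0,
    maxiter: int = 500,
) -> SiteModelFit:
    """Two-ratio branch model.

    ``foreground_branches`` names the branches (by child tip or internal
    node label) whose omega is free; the rest form the background.  With
    ``background_omega`` set (default 1, the neutral-background variant)
    the background ratio is fixed; pass None to estimate it freely.  If
    ``foreground_branches`` is None every branch is foreground and the
    model collapses to M0 on fixed branch lengths.
    """
    if m0 is None:
        m0 = fit_m0(aln, tree, n_starts=1, seed=seed, maxiter=maxiter)
    freqs = m0.freqs
    lik = CodonLikelihood(aln, tree)
    blen = m0.branch_lengths
    if foreground_branches is None:
        fg = np.ones(lik.n_branches, dtype=bool)
    else:
        fg = _branch_mask(lik, tree, set(foreground_branches))
        if not fg.any():
            raise ValidationError(
                f"no branch labelled with any of {sorted(foreground_branches)}"
            )
    unidentifiable = bool(blen[fg].sum() <= 1e-12)
    free_bg = background_omega is None and not fg.all()

    def omegas(x):
        w = np.empty(lik.n_branches)
        w[fg] = np.exp(x[1])
        if fg.all():
            return w
        w[~fg] = np.exp(x[2]) if free_bg else background_omega
        return w

    def neg(x):
        return -lik.loglik_branchwise(np.exp(x[0]), omegas(x), freqs, blen)

    neg = _safe(neg)
    x0 = [np.log(m0.kappa), np.log(max(m0.omega, 1e-3))]
    if free_bg:
        x0.append(np.log(max(m0.omega, 1e-3)))
    res = _minimize(neg, np.array(x0), maxiter)
    w_fg = float(np.exp(res.x[1]))
    w_bg = float(np.exp(res.x[2])) if free_bg else (
        background_omega if not fg.all() else w_fg
    )
    return SiteModelFit(
        model="branch",
        lnL=-float(res.fun),
        kappa=float(np.exp(res.x[0])),
        omega_classes=[(float(fg.mean()), w_fg), (float(1 - fg.mean()), w_bg)],
        n_params=MODEL_N_PARAMS["branch"],
        branch_lengths=blen,
        freqs=freqs,
        converged=bool(res.success),
        foreground_unidentifiable=unidentifiable,
    )


def lrt(null: SiteModelFit, alt: SiteModelFit) -> LRTResult:
    """Likelihood-ratio test between nested codon models.

    The statistic 2(lnL_alt - lnL_null) is clamped at zero (the boundary
    case where the alternative collapses onto the null) and referred to a
    chi-square with df equal to the difference in omega-distribution
    parameter counts.
    """
    if (null.model, alt.model) not in _NESTED_PAIRS:
        raise ValidationError(f"{null.model} is not nested in {alt.model}")
    df = alt.n_params - null.n_params
    statistic = max(0.0, 2.0 * (alt.lnL - null.lnL))
    p = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return LRTResult(
        lnL_null=null.lnL, lnL_alt=alt.lnL, statistic=statistic, df=df, p_value=p
    )
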