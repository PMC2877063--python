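"""Self-contained validation experiments for the pipeline's core claims.

Each function generates its own inputs (synthetic data or the published
reference counts), runs the relevant method, and returns a measured
quantity.  They are used both by the test suite and by the reproduction
script, and are deliberately sized for a single desktop CPU: problem
sizes are stated in the methods note.
"""

from __future__ import annotations

import itertools

import numpy as np

from .clock import Calibration, ClockModel, effective_sample_size, run_mcmc, summarize
from .clock import _node_ages_from_durations  # noqa: F401  (summary truth helper)
from .codes import MITO_CODE
from .codonmodel import CodonLikelihood, ReversibleEigen, gy94_matrix
from .compstats import composition
from .divergence import count_variation, global_align, ng86_dnds
from .genome import extract_gene
from .reference import reference_profiles
from .selection import fit_m0, fit_site_model, lrt
from .simulate import (
    ClockSimSpec,
    CodonSimSpec,
    MitoSimSpec,
    mutate_genotype_pair,
    simulate_clock_alignment,
    simulate_codon_alignment,
    simulate_mitogenome,
)
from .trees import PhyloTree

TREE4 = "((A:0.15,B:0.15):0.08,(C:0.15,D:0.15):0.08);"
TIME_TREE = "((A:40,B:40):60,(C:70,D:70):30);"


# ---------------------------------------------------------------------------
# Composition worked examples (published base counts as inputs)


def reference_composition_report() -> dict[str, float]:
    """Recompute printed AT% and skews from the published base counts."""
    profs = reference_profiles()
    return {
        "darlingi_N_at_percent": profs["Anopheles darlingi N"].reported()["at_percent"],
        "darlingi_N_g_skew": profs["Anopheles darlingi N"].reported()["g_skew"],
        "gambiae_g_skew": profs["Anopheles gambiae"].reported()["g_skew"],
        "gambiae_t_skew": profs["Anopheles gambiae"].reported()["t_skew"],
        "quadrimaculatus_g_skew": profs["Anopheles quadrimaculatus"].reported()["g_skew"],
        "funestus_t_skew": profs["Anopheles funestus"].reported()["t_skew"],
        "albopictus_at_percent": profs["Aedes albopictus"].reported()["at_percent"],
        "yakuba_g_skew": profs["Drosophila yakuba"].reported()["g_skew"],
    }


# ---------------------------------------------------------------------------
# Stand-in genome geometry (synthetic rendering of the deposited record)


def standin_genome_geometry(seed: int = 1) -> dict[str, float]:
    """Geometry of the synthetic stand-in for the deposited mitogenome."""
    genome, table = simulate_mitogenome(MitoSimSpec(seed=seed))
    from .genome import FeatureKind

    counts = {
        "genome_length_bp": genome.length,
        "n_trna": len(table.by_kind(FeatureKind.TRNA)),
        "n_pcg": len(table.pcgs),
        "n_rrna": len(table.by_kind(FeatureKind.RRNA)),
        "at_percent": composition(genome.sequence).reported()["at_percent"],
    }
    return counts


# ---------------------------------------------------------------------------
# selection_ml: pruning vs enumeration, M0 recovery, LRT type-I rate


def _enumeration_loglik(lik: CodonLikelihood, kappa, omega, freqs, blen) -> float:
    """Likelihood by explicit summation over internal-node codon states."""
    arr = lik.arrays
    eig = ReversibleEigen.from_q(gy94_matrix(freqs, kappa, omega, lik.code), freqs)
    Ps = [eig.transition(t) for t in blen]
    internals = list(range(arr.n_tips, arr.n_nodes))
    n_states = len(freqs)
    total = 0.0
    for s in range(lik.patterns.shape[1]):
        tip_states = lik.patterns[:, s]
        site_lik = 0.0
        for assign in itertools.product(range(n_states), repeat=len(internals)):
            node_state = dict(zip(internals, assign))
            for tip in range(arr.n_tips):
                node_state[tip] = tip_states[tip]
            p = freqs[node_state[arr.root]]
            for node in range(arr.n_nodes - 1):
                p *= Ps[node][node_state[arr.parent[node]], node_state[node]]
            site_lik += p
        total += lik.weights[s] * np.log(site_lik)
    return total


_SMALL_TREES = {
    2: "(A:{0},B:{1});",
    3: "(A:{0},B:{1},C:{2});",
    4: "(A:{0},B:{1},(C:{2},D:{3}):{4});",
}


def pruning_enumeration_max_diff(n_instances: int = 200, seed: int = 0) -> float:
    """Max |pruning - enumeration| log-likelihood over random small instances
    (2-4 taxa, 1-3 codon sites, random parameters)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n_taxa = int(rng.integers(2, 5))
        n_branch = {2: 2, 3: 3, 4: 5}[n_taxa]
        blen = rng.uniform(0.01, 0.6, n_branch)
        nwk = _SMALL_TREES[n_taxa].format(*blen)
        tree = PhyloTree.from_newick(nwk)
        aln = simulate_codon_alignment(
            CodonSimSpec(
                seed=int(rng.integers(2**31 - 1)),
                tree=tree,
                n_codons=int(rng.integers(1, 4)),
            )
        )
        lik = CodonLikelihood(aln, tree)
        freqs = rng.dirichlet(np.ones(62))
        kappa = float(rng.uniform(0.5, 5))
        omega = float(rng.uniform(0.02, 3))
        b = rng.uniform(0.01, 0.6, lik.n_branches)
        fast = lik.loglik_single(kappa, omega, freqs, b)
        slow = _enumeration_loglik(lik, kappa, omega, freqs, b)
        worst = max(worst, abs(fast - slow))
    return worst


def m0_omega_recovery(
    seed: int = 0, true_omega: float = 0.1, n_codons: int = 5000
) -> float:
    """Fit M0 to data simulated at a known omega; return the estimate."""
    tree = PhyloTree.from_newick(TREE4)
    aln = simulate_codon_alignment(
        CodonSimSpec(
            seed=seed, tree=tree, kappa=2.0,
            site_classes=((1.0, true_omega),), n_codons=n_codons,
        )
    )
    return fit_m0(aln, tree, n_starts=1).omega


def m1a_m2a_type1_rate(
    n_reps: int = 100, n_codons: int = 200, seed: int = 0, alpha: float = 0.05
) -> float:
    """Fraction of M1a-simulated datasets where the M1a-vs-M2a LRT rejects.

    Uses single-start fits (reduced restarts) sized for one CPU.
    """
    tree = PhyloTree.from_newick(TREE4)
    rejections = 0
    for rep in range(n_reps):
        aln = simulate_codon_alignment(
            CodonSimSpec(
                seed=seed + rep, tree=tree, kappa=2.0,
                site_classes=((0.95, 0.05), (0.05, 1.0)), n_codons=n_codons,
            )
        )
        m0 = fit_m0(aln, tree, n_starts=1, maxiter=200)
        m1a = fit_site_model(aln, tree, "M1a", m0=m0, n_starts=1, maxiter=200)
        m2a = fit_site_model(aln, tree, "M2a", m0=m0, n_starts=1, maxiter=200)
        if lrt(m1a, m2a).p_value < alpha:
            rejections += 1
    return rejections / n_reps


# ---------------------------------------------------------------------------
# clock_dating: prior recovery, HPD coverage, ESS calibration


def prior_recovery_error(seed: int = 0) -> dict[str, float]:
    """Prior-only MCMC: sampled root age vs its normal calibration prior."""
    tree = PhyloTree.from_newick(TIME_TREE, rooted=True)
    clock = ClockModel(kind="strict", rate_prior_mean=0.01, rate_prior_sd=0.005)
    cal_mean, cal_sd = 100.0, 2.0
    trace = run_mcmc(
        None, tree, clock,
        [Calibration.of(("A", "B", "C", "D"), cal_mean, cal_sd)],
        generations=40_000, thinning=20, seed=seed, birth_rate=0.01,
    )
    from .trees import tree_to_arrays

    arr = tree_to_arrays(tree)
    x = trace.post_burn_in(0.25)[f"age_node{arr.root}"].to_numpy()
    return {
        "mean_error": float(abs(x.mean() - cal_mean)),
        "sd_error": float(abs(x.std() - cal_sd)),
    }


def strict_clock_hpd_coverage(
    n_reps: int = 20, seed: int = 0, n_sites: int = 1000, generations: int = 20_000
) -> float:
    """Fraction of (replicate, internal node) pairs whose true age falls
    inside the 95% HPD of a strict-clock posterior."""
    tree = PhyloTree.from_newick(TIME_TREE, rooted=True)
    clock = ClockModel(kind="strict", rate_prior_mean=0.01, rate_prior_sd=0.005)
    cal = [Calibration.of(("A", "B", "C", "D"), 100.0, 5.0)]
    covered = total = 0
    for rep in range(n_reps):
        sim = simulate_clock_alignment(
            ClockSimSpec(
                seed=seed + 1000 + rep, time_tree=tree, clock="strict",
                mean_rate=0.01, n_sites=n_sites,
            )
        )
        trace = run_mcmc(
            sim.alignment, tree, clock, cal,
            generations=generations, thinning=20, seed=seed + rep,
        )
        summ = summarize(trace)
        truth = _node_ages_from_durations(sim.arrays)
        for node_name, (lo, hi) in summ.hpd95.items():
            idx = int(node_name.replace("node", ""))
            total += 1
            if lo <= truth[idx] <= hi:
                covered += 1
    return covered / total


def ar1_ess_ratio(seed: int = 0, n: int = 20_000, rho: float = 0.9) -> float:
    """ESS estimate on a synthetic AR(1) chain divided by the analytic value
    n(1-rho)/(1+rho)."""
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = 0.0
    noise = rng.normal(size=n) * np.sqrt(1 - rho * rho)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + noise[i]
    return effective_sample_size(x) / (n * (1 - rho) / (1 + rho))


# ---------------------------------------------------------------------------
# pairwise_divergence: pathway oracle, alignment oracle, planted CR events


def ng86_pathway_max_diff() -> float:
    """Max |implementation - brute force| over every two-difference sense
    codon pair (pathway enumeration oracle)."""
    code = MITO_CODE
    sense = code.sense_codons
    worst = 0.0
    for c1 in sense:
        for c2 in sense:
            if sum(a != b for a, b in zip(c1, c2)) != 2:
                continue
            r = ng86_dnds(c1, c2, code)
            paths = []
            diff = [i for i in range(3) if c1[i] != c2[i]]
            for order in itertools.permutations(diff):
                cur, syn, nonsyn, ok = c1, 0, 0, True
                for pos in order:
                    nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                    if code.is_stop(nxt) and nxt != c2:
                        ok = False
                        break
                    if (
                        not code.is_stop(nxt)
                        and code.codon_to_aa[cur] == code.codon_to_aa[nxt]
                    ):
                        syn += 1
                    else:
                        nonsyn += 1
                    cur = nxt
                if ok:
                    paths.append((syn, nonsyn))
            if paths:
                syn = sum(p[0] for p in paths) / len(paths)
                nonsyn = sum(p[1] for p in paths) / len(paths)
                worst = max(worst, abs(r.Sd - syn), abs(r.Nd - nonsyn))
    return worst


def alignment_oracle_max_diff(n_instances: int = 200, seed: int = 0) -> float:
    """Max |score difference| between the package aligner and an independent
    affine-gap dynamic-programming implementation on random short strings."""
    from Bio import Align

    pa = Align.PairwiseAligner(
        match_score=1, mismatch_score=-1, open_gap_score=-5,
        extend_gap_score=-1, mode="global",
    )
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n1, n2 = rng.integers(1, 25, 2)
        a = "".join(rng.choice(list("ACGT"), n1))
        b = "".join(rng.choice(list("ACGT"), n2))
        worst = max(worst, abs(global_align(a, b).score - pa.score(a, b)))
    return worst


def planted_cr_variation(seed: int = 1) -> tuple[int, int, int]:
    """Variable sites / substitutions / indel events recovered by aligning
    the control regions of a genotype pair planted with 6 substitutions and
    9 indels (the study's reported CR variation pattern)."""
    genome, table = simulate_mitogenome(MitoSimSpec(seed=seed))
    g2, t2 = mutate_genotype_pair(
        genome, table, n_cds_subs=10, n_cr_subs=6, n_cr_indels=9, seed=seed + 1
    )
    cr1 = extract_gene(genome, table.control_region)
    cr2 = extract_gene(g2, t2.control_region)
    return count_variation(global_align(cr1, cr2))
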