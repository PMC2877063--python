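"""GTR+Gamma likelihood, calibrated MCMC dating, traces and diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mitocomp import (
    Calibration,
    ClockModel,
    ClockSimSpec,
    GTRParams,
    McmcTrace,
    PhyloTree,
    combine_traces,
    effective_sample_size,
    fit_rate_multiplier,
    gtr_gamma_lnL,
    hpd_interval,
    partition_alignment,
    run_mcmc,
    simulate_clock_alignment,
    summarize,
)
from mitocomp.clock import NucLikelihood, mrca_index, yule_log_prior
from mitocomp.codonmodel import ReversibleEigen
from mitocomp.simulate import discrete_gamma_rates, gtr_q
from mitocomp.trees import tree_to_arrays
from mitocomp.genome import ValidationError

TIME_TREE = "((A:40,B:40):60,(C:70,D:70):30);"


class TestGtrGammaLikelihood:
    def test_zero_branch_identical_pair_closed_form(self):
        tree = PhyloTree.from_newick("(A:0.0,B:0.0);", rooted=True)
        aln = {"A": "ACGTT", "B": "ACGTT"}
        params = GTRParams(freqs=(0.3, 0.2, 0.2, 0.3))
        ll = gtr_gamma_lnL(aln, tree, params)
        f = {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}
        assert ll == pytest.approx(sum(np.log(f[c]) for c in "ACGTT"))

    def test_enumeration_oracle_three_taxa(self):
        tree = PhyloTree.from_newick("(A:0.3,B:0.2,C:0.5);")
        aln = {"A": "AC", "B": "AG", "C": "TC"}
        params = GTRParams(
            rates=(1.2, 2.5, 0.8, 1.1, 3.0, 1.0),
            freqs=(0.3, 0.2, 0.2, 0.3), gamma_shape=0.7,
        )
        fast = gtr_gamma_lnL(aln, tree, params)
        f = np.array(params.freqs)
        eig = ReversibleEigen.from_q(gtr_q(params), f)
        rates = discrete_gamma_rates(0.7, 4)
        arr = tree_to_arrays(tree)
        nt = {"A": 0, "C": 1, "G": 2, "T": 3}
        slow = 0.0
        for site in range(2):
            site_lik = 0.0
            for r in rates:
                Ps = [eig.transition(arr.blen[i] * r) for i in range(3)]
                states = [nt[aln[lab][site]] for lab in arr.tip_labels]
                site_lik += sum(
                    f[root] * Ps[0][root, states[0]] * Ps[1][root, states[1]]
                    * Ps[2][root, states[2]]
                    for root in range(4)
                ) / len(rates)
            slow += np.log(site_lik)
        assert fast == pytest.approx(slow, abs=1e-10)

    def test_single_category_equals_plain_gtr(self):
        tree = PhyloTree.from_newick("(A:0.2,B:0.3);")
        rng = np.random.default_rng(1)
        aln = {
            "A": "".join(rng.choice(list("ACGT"), 50)),
            "B": "".join(rng.choice(list("ACGT"), 50)),
        }
        plain = GTRParams()
        one_cat = GTRParams(gamma_shape=0.5, gamma_categories=1)
        # a single equal-probability category has rate exactly 1
        assert gtr_gamma_lnL(aln, tree, one_cat) == pytest.approx(
            gtr_gamma_lnL(aln, tree, plain)
        )

    def test_invariant_sites_increase_constant_site_likelihood(self):
        tree = PhyloTree.from_newick("(A:0.5,B:0.5);")
        aln = {"A": "AAAA", "B": "AAAA"}
        base = gtr_gamma_lnL(aln, tree, GTRParams())
        with_inv = gtr_gamma_lnL(aln, tree, GTRParams(p_invariant=0.5))
        assert with_inv > base


@pytest.fixture(scope="module")
def strict_run():
    tree = PhyloTree.from_newick(TIME_TREE, rooted=True)
    sim = simulate_clock_alignment(
        ClockSimSpec(seed=3, time_tree=tree, clock="strict",
                     mean_rate=0.01, n_sites=1000)
    )
    clock = ClockModel(kind="strict", rate_prior_mean=0.01, rate_prior_sd=0.005)
    cal = [Calibration.of(("A", "B", "C", "D"), 100.0, 5.0)]
    trace = run_mcmc(
        sim.alignment, tree, clock, cal,
        generations=20_000, thinning=20, seed=5,
    )
    return tree, sim, trace


class TestMcmc:
    def test_age_order_constraints_never_violated(self, strict_run):
        tree, sim, trace = strict_run
        df = trace.samples
        arr = sim.arrays
        # the root must always be older than both child clades
        root_col = [c for c in trace.age_columns if c.endswith(str(arr.root))][0]
        others = [c for c in trace.age_columns if c != root_col]
        for c in others:
            assert (df[root_col] >= df[c] - 1e-12).all()

    def test_true_ages_recovered_in_hpd(self, strict_run):
        tree, sim, trace = strict_run
        summ = summarize(trace)
        arr = sim.arrays
        from mitocomp.clock import _node_ages_from_durations

        truth = _node_ages_from_durations(arr)
        for node_name, (lo, hi) in summ.hpd95.items():
            idx = int(node_name.replace("node", ""))
            assert lo - 1 <= truth[idx] <= hi + 1, (node_name, truth[idx], lo, hi)

    def test_deterministic_trace(self):
        tree = PhyloTree.from_newick(TIME_TREE, rooted=True)
        clock = ClockModel(kind="strict", rate_prior_mean=0.01, rate_prior_sd=0.005)
        cal = [Calibration.of(("A", "B", "C", "D"), 100.0, 5.0)]
        t1 = run_mcmc(None, tree, clock, cal, generations=2000, thinning=10, seed=4)
        t2 = run_mcmc(None, tree, clock, cal, generations=2000, thinning=10, seed=4)
        pd.testing.assert_frame_equal(t1.samples, t2.samples)

    def test_no_calibration_refused(self):
        tree = PhyloTree.from_newick(TIME_TREE, rooted=True)
        clock = ClockModel(kind="strict")
        with pytest.raises(ValidationError):
            run_mcmc(None, tree, clock, [], generations=100, thinning=10, seed=0)

    def test_tip_calibration_refused(self):
        tree = PhyloTree.from_newick(TIME_TREE, rooted=True)
        clock = ClockModel(kind="strict")
        with pytest.raises(ValidationError):
            run_mcmc(
                None, tree, clock, [Calibration.of(("A",), 10.0, 1.0)],
                generations=100, thinning=10, seed=0,
            )

    def test_prior_only_yule_ranked_ages_match_forward_simulation(self):
        """Prior-only MCMC on a fixed topology must reproduce the ranked
        node-age distribution of the pure-birth process conditioned on the
        root age and tip count (forward rejection-sampling oracle)."""
        lam = 0.02
        root_age = 100.0
        n_tips = 5
        tree = PhyloTree.from_newick(
            "((A:40,B:40):60,((C:30,D:30):40,E:70):30);", rooted=True
        )
        clock = ClockModel(kind="strict", rate_prior_mean=0.01, rate_prior_sd=0.005)
        cal = [Calibration.of(("A", "B", "C", "D", "E"), root_age, 1e-6)]
        trace = run_mcmc(
            None, tree, clock, cal, generations=60_000, thinning=20,
            seed=11, birth_rate=lam,
        )
        df = trace.post_burn_in(0.25)
        sampled = df[list(trace.age_columns)].to_numpy()
        root_idx = int(np.argmax(sampled.mean(axis=0)))
        non_root = np.delete(sampled, root_idx, axis=1)
        mcmc_ranked = np.sort(non_root, axis=1)

        # forward pure-birth oracle: 2 lineages at root_age, accept paths
        # with exactly n_tips at present
        rng = np.random.default_rng(12)
        acc = []
        while len(acc) < 3000:
            t = root_age
            k = 2
            events = []
            while True:
                t -= rng.exponential(1.0 / (k * lam))
                if t <= 0:
                    break
                k += 1
                events.append(t)
                if k > n_tips:
                    break
            if k == n_tips and t <= 0:
                acc.append(sorted(events))
        oracle_ranked = np.array(acc)
        for j in range(n_tips - 2):
            s, o = mcmc_ranked[:, j], oracle_ranked[:, j]
            assert abs(np.mean(s) - np.mean(o)) < 4.0, j

    def test_prior_only_calibration_recovery(self):
        tree = PhyloTree.from_newick(TIME_TREE, rooted=True)
        clock = ClockModel(kind="strict", rate_prior_mean=0.01, rate_prior_sd=0.005)
        cal = [Calibration.of(("A", "B", "C", "D"), 100.0, 2.0)]
        trace = run_mcmc(
            None, tree, clock, cal, generations=40_000, thinning=20,
            seed=5, birth_rate=0.01,
        )
        arr = tree_to_arrays(tree)
        x = trace.post_burn_in(0.25)[f"age_node{arr.root}"]
        assert abs(x.mean() - 100.0) < 0.6
        assert abs(x.std() - 2.0) < 0.6


class TestTraces:
    def _mk_trace(self, values, thinning=1):
        df = pd.DataFrame({"age_node4": values})
        df.index.name = "generation"
        return McmcTrace(
            samples=df, generations=len(values), thinning=thinning,
            age_columns=("age_node4",),
        )

    def test_combine_identity(self):
        t = self._mk_trace(np.arange(200.0))
        c = combine_traces([t], burn_in=0.0)
        assert len(c.samples) == 200

    def test_combine_concatenates_post_burn_in(self):
        traces = [self._mk_trace(np.arange(400.0)) for _ in range(3)]
        c = combine_traces(traces, burn_in=0.75)
        assert len(c.samples) == 300

    def test_combined_ess_at_least_single_run(self):
        rng = np.random.default_rng(0)
        traces = [self._mk_trace(rng.normal(size=2000)) for _ in range(3)]
        singles = [
            effective_sample_size(t.post_burn_in(0.0)["age_node4"].to_numpy())
            for t in traces
        ]
        c = combine_traces(traces, burn_in=0.0)
        combined = effective_sample_size(c.samples["age_node4"].to_numpy())
        assert combined >= max(singles)

    def test_schema_mismatch_rejected(self):
        t1 = self._mk_trace(np.arange(100.0))
        df = pd.DataFrame({"other": np.arange(100.0)})
        t2 = McmcTrace(samples=df, generations=100, thinning=1)
        with pytest.raises(ValidationError):
            combine_traces([t1, t2])


class TestSummaries:
    def test_iid_normal_ess_and_hpd(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=10_000)
        ess = effective_sample_size(x)
        assert 8000 <= ess <= 12000
        lo, hi = hpd_interval(x)
        assert lo == pytest.approx(-1.96, abs=0.1)
        assert hi == pytest.approx(1.96, abs=0.1)

    def test_ar1_ess_matches_analytic(self):
        rng = np.random.default_rng(7)
        n, rho = 20_000, 0.9
        x = np.empty(n)
        x[0] = 0.0
        noise = rng.normal(size=n) * np.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + noise[i]
        ess = effective_sample_size(x)
        analytic = n * (1 - rho) / (1 + rho)
        assert abs(ess - analytic) / analytic < 0.3

    def test_constant_chain_degenerate(self):
        df = pd.DataFrame({"age_root": np.full(500, 42.0)})
        trace = McmcTrace(samples=df, generations=500, thinning=1,
                          age_columns=("age_root",))
        s = summarize(trace, burn_in=0.0)
        assert s.hpd95["root"] == (42.0, 42.0)
        assert "age_root" in s.degenerate

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({"age_root": np.arange(50.0)})
        trace = McmcTrace(samples=df, generations=50, thinning=1)
        with pytest.raises(ValidationError):
            summarize(trace, burn_in=0.0)


class TestPartitions:
    def test_nine_codon_gene_split(self):
        aln = {"A": "ACG" * 9, "B": "ACG" * 9}
        parts = partition_alignment(aln)
        assert len(parts["pos12"]) == 18
        assert len(parts["pos3"]) == 9

    def test_union_is_all_sites_and_disjoint(self):
        aln = {"A": "ACGTAA", "B": "ACGTAA"}
        parts = partition_alignment(aln)
        union = np.sort(np.concatenate([parts["pos12"], parts["pos3"]]))
        assert np.array_equal(union, np.arange(6))
        assert not set(parts["pos12"]) & set(parts["pos3"])

    def test_frame_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            partition_alignment({"A": "ACGTA", "B": "ACGTA"})

    def test_faster_third_positions_recovered(self):
        # simulate codon data (3rd positions evolve faster under omega<1)
        from mitocomp import CodonSimSpec, simulate_codon_alignment

        tree = PhyloTree.from_newick("((A:0.3,B:0.3):0.15,(C:0.3,D:0.3):0.15);")
        caln = simulate_codon_alignment(
            CodonSimSpec(seed=13, tree=tree, site_classes=((1.0, 0.05),),
                         n_codons=400)
        )
        aln = {t: caln.codon_strings(t) for t in caln.taxa}
        parts = partition_alignment(aln)
        params = GTRParams()
        c12 = fit_rate_multiplier(aln, tree, params, parts["pos12"])
        c3 = fit_rate_multiplier(aln, tree, params, parts["pos3"])
        assert c3 / c12 > 1.0
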