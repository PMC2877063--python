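# mitocomp

Comparative mitogenomics of anopheline mosquitoes, built around the kind of
analysis used to characterise the *Anopheles darlingi* mitochondrial genome:
genome-architecture and base-composition descriptors, codon usage, per-gene
divergence and dN/dS, maximum-likelihood codon site models for positive
selection, and calibrated Bayesian relaxed-clock divergence dating.

The package is aimed at molecular entomologists and phylogeneticists who
want each of these stages as a tested, scriptable library rather than a
chain of GUI tools — and at method developers who need a synthetic data
generator that produces realistic inputs for every stage (a 37-gene
circular mitogenome with strand-specific genes, reading-frame overlaps,
incomplete stop codons and an AT-rich control region; codon alignments
evolved under known selection regimes; clock trees with known node ages and
rates), so the whole pipeline is testable without sequence downloads.

## The models

**Strand asymmetry.** Composition bias between the two mtDNA strands is
summarised by the skews

```
G-skew = (G − C) / (G + C)        T-skew = (T − A) / (T + A)
```

computed on the majority (H) strand. Insect mtDNA is A+T rich (~78% here)
with negative skews on both axes.

**Codon usage.** RSCU(c) = count(c) / mean count over c's synonymous
family, under the invertebrate mitochondrial code (table 5: TGA=Trp,
ATA=Met, AGA/AGG=Ser; stops TAA/TAG only).

**Pairwise dN/dS.** Nei–Gojobori (1986) counting: fractional synonymous
site potential per codon, equal-weight averaging over minimal substitution
pathways for multi-difference codons (stop-codon intermediates excluded),
and Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3) applied to pN and pS.

**Site models.** Goldman–Yang (GY94) codon substitution process with
transition/transversion ratio κ and selection parameter ω, fitted by
maximum likelihood under the standard random-sites models M0 (one ratio),
M1a (nearly neutral), M2a (selection), M7 (beta) and M8 (beta&ω), with
F3×4 codon frequencies and likelihood-ratio tests (df = 2 for M1a–M2a and
M7–M8). A two-ratio branch model (foreground vs background ω) is included.

**Divergence dating.** Fixed rooted topology; node ages sampled by MCMC
under a GTR+Γ(+I) likelihood with branch length = rate × duration, a
strict or uncorrelated-lognormal clock, a Yule (pure-birth) tree prior and
normal calibration priors on chosen clades. Traces are summarised by
posterior means, 95% HPD intervals and autocorrelation-based ESS.

## Worked example

```python
import mitocomp as mc

# a synthetic mitogenome pair: northern/southern-style genotypes
g1, t1 = mc.simulate_mitogenome(mc.MitoSimSpec(seed=1))
g2, t2 = mc.mutate_genotype_pair(g1, t1, n_cds_subs=10,
                                 n_cr_subs=6, n_cr_indels=9, seed=2)

print(g1.length)                       # 15386
prof = mc.composition(g1.sequence)
print(prof.reported()["at_percent"])   # 78.0

cr1 = mc.extract_gene(g1, t1.control_region)
cr2 = mc.extract_gene(g2, t2.control_region)
print(mc.poly_t_stretch(cr1, 5))       # (142, 17)  — planted T-stretch
aln = mc.global_align(cr1, cr2)
print(mc.count_variation(aln))         # (15, 6, 9) — sites, subs, indels
```

The composition line says the genome is 78.0% A+T; the control-region
comparison recovers exactly the planted variation: 15 variable sites, of
which 9 are indel events — the pattern reported for the two *An. darlingi*
genotypes.

Fitting a site model to a simulated alignment:

```python
tree = mc.PhyloTree.from_newick("((A:0.15,B:0.15):0.08,(C:0.15,D:0.15):0.08);")
aln = mc.simulate_codon_alignment(mc.CodonSimSpec(
    seed=2, tree=tree, site_classes=((1.0, 0.1),), n_codons=5000))
fit = mc.fit_m0(aln, tree)
print(round(fit.omega, 3))             # 0.098 — recovers the simulated 0.1
```

A command-line interface mirrors the library
(`mitocomp simulate|stats|compare|selection|date|run|validate`); all
tabular outputs are tab-separated with `#` provenance headers.

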