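# Methods

This note documents the models, conventions, numerical choices and known
limitations of `mitocomp`, stage by stage.

## Genome representation and the feature template

Coordinates are 1-based inclusive on the strand as written in the FASTA
record (the majority/H strand), matching GenBank convention; L-strand
genes are read as the reverse complement of their coordinate slice.
Origin-spanning features are rejected — the anopheline gene arrangement
annotates none — and this is a documented limitation for taxa whose
control region wraps the origin.

The canonical 37-gene template (`mitocomp.template`) encodes the
*Anopheles darlingi*-style architecture: 13 protein-coding genes on both
strands, 22 tRNAs, 2 rRNAs, one AT-rich control region, the ATP8/ATP6 and
NAD4/NAD4L 7-nt reading-frame overlaps, and incomplete stop codons (TA on
NAD4/NAD5, T on COI/COII/COIII) that are completed by polyadenylation and
therefore padded with A before translation. Two template boundaries are
shifted relative to the published span list (COI end 2963→2961, NAD4
start 8103→8102) because the printed spans are incompatible with their
own incomplete-stop annotations (a span of length L can carry a k-nt
incomplete stop only when L ≡ k mod 3); the printed size column also
disagrees with its own coordinates for one tRNA, and coordinates are
always taken as authoritative.

The invertebrate mitochondrial code (NCBI table 5) is used throughout: 62
sense codons, stops TAA/TAG, TGA=Trp, ATA=Met, AGA/AGG=Ser. Accepted
initiators are the ATN family plus GTG and TCG (the anopheline COI
start). Codons containing N translate to X and are excluded from
codon-usage and dN/dS counting.

## Synthetic mitogenome generator

`simulate_mitogenome` realises the template as follows: protein-gene
start/stop codons are first pinned into the genome buffer (strand-aware),
reconciling overlapping reading frames; gene bodies are then filled codon
by codon, sampling from the base-composition target (default 78% AT,
roughly the anopheline genome average) subject to the pinned letters and
to stop-codon avoidance, by enumerating the consistent codons and
sampling them with composition weights. The control region is filled at
its own AT target (default 93.6%) around a planted poly-T stretch
(default 17 nt at control-region position 142, the conserved regulatory
motif position); remaining positions (tRNAs, rRNAs, spacers) are filled
at the genome composition. Composition bias therefore enters through
stationary base frequencies, not mutation asymmetry — sufficient for
exercising composition/skew descriptors, not a mechanistic strand-bias
model.

`mutate_genotype_pair` derives a second genotype with exact, countable
differences: coding substitutions avoid start/stop codons, positions
shared by two features, and never create internal stops; control-region
edits are n substitutions plus m indels of 1–3 nt (the study reports only
event counts, so indel lengths are a modelling choice). In ~94% AT
sequence, nearby opposite-sign indels can be re-explained by an optimal
aligner as substitutions, so the generator verifies its own plant: it
aligns the edited control region against the original and redraws
positions (deterministically, from the seed) until the alignment recovers
exactly the planted counts. Edits are spaced ≥12 nt apart and avoid the
poly-T stretch, whose internal edits would be alignment-ambiguous.

Codon alignments (`simulate_codon_alignment`) draw each site's ω class by
its proportion and evolve sites down the tree using exact
matrix-exponential transition probabilities per branch (not event-by-event
simulation) — faster and exactly distribution-correct. Clock alignments
(`simulate_clock_alignment`) evolve under GTR with optional discrete-gamma
rate variation and invariant sites; branch lengths are rate × duration
with strict or lognormal per-branch rates (lognormal parameterised so the
expected rate equals the nominal mean). All generators are
bit-reproducible given (spec, seed).

## Composition statistics

Skews are (G−C)/(G+C) and (T−A)/(T+A) on the H strand — the orientation
that reproduces every published comparative value. Printed values
truncate toward zero (3 decimals for skews, 1 for percentages); this is
the only convention consistent with the published table (e.g.
−0.1449 → −0.144), and full precision is always retained on the objects.
Undefined skews (no G+C, or no A+T) are flagged as missing, not zero.
Sliding windows honour circularity by wrapping; the window count for a
circular genome is ceil(L/step). Codon usage aggregates the 13
protein-coding genes on their coding strands: complete terminal stops are
counted but excluded from the non-stop total, padded incomplete stops are
excluded entirely, and overlapping genes are counted independently
(codons in the ATP8/ATP6 overlap contribute to both genes), mirroring
per-gene tallies. RSCU is count over family mean with stop codons outside
families; an unobserved family has undefined (not zero) RSCU.

## Pairwise divergence

The aligner is a Needleman–Wunsch/Gotoh global aligner with affine gaps
(gap of length k costs open + (k−1)·extend; defaults +1/−1/−5/−1).
Traceback ties prefer the diagonal, then a gap in the first sequence.
Percent identity counts matches over columns including internal gap
columns but excluding terminal overhangs (the published identity table's
procedure is unstated; this convention is fixed here). Variation counting
treats a maximal run of gap columns in one row as one indel event and one
variable site, so variable sites = substitutions + indel events —
matching how control-region variation is reported (15 sites including 9
indels).

NG86 dN/dS follows the counting method exactly as specified: per-codon
fractional synonymous site potential (changes into stop codons count as
nonsynonymous, so N+S = 3×codons), equal-weight averaging over minimal
substitution pathways with stop-passing pathways excluded (falling back
to all pathways only when every ordering is blocked), Jukes–Cantor
correction on both proportions, and ω undefined when dS = 0 or p ≥ 3/4.
One consequence worth knowing: pathway averaging can attribute a small
Nd to codon pairs that are synonymous at the endpoints (e.g. TTA↔CTC,
both Leu, where one of the two minimal paths crosses Phe), so Nd is not
exactly zero even for data evolved at ω=0; the endpoint amino acids are.
The quick age conversion divides percent divergence by the standard
arthropod mtDNA rate of 2.3% per million years.

## Codon site models

The GY94 rate matrix over the 62 sense codons has q_ij = π_j ·
κ^[transition] · ω^[nonsynonymous] for single-nucleotide changes, scaled
to one expected substitution per codon per unit branch length at the
given ω. Codon frequencies are F3×4 with a 0.5 pseudocount per position
class (degenerate alignments stay usable). Likelihoods use Felsenstein
pruning over compressed site patterns with per-node rescaling; the
process is reversible, so transition matrices come from a symmetrised
eigendecomposition and the likelihood is invariant to root placement.

Fitting is bounded quasi-Newton (L-BFGS-B) on log/logit-transformed
parameters with configurable random restarts (default 3; the large
replicated experiments use 1). M0 estimates κ, ω and branch lengths
jointly; the richer models then hold M0's branch lengths fixed by default
(the usual protocol of seeding site models with one-ratio branch
lengths), with joint estimation available via a flag. M7/M8 discretise
Beta(p, q) into K=10 equal-probability classes represented by their
conditional means; p and q are bounded to [0.005, 99]. M2a's extra class
is constrained to ω ≥ 1, as is M8's. LRT statistics are clamped at zero
and referred to χ² with df equal to the difference in ω-distribution
parameter counts (2 for M1a–M2a and M7–M8); the boundary-mixture
refinement of the null is noted but not the default, which makes the test
conservative.

The branch model fixes the background ratio (default ω=1, the
neutral-background variant described for this analysis — an unusual
constraint, retained as specified) and frees the foreground ratio;
passing `background_omega=None` gives the conventional free-background
two-ratio model. A foreground consisting only of zero-length branches is
flagged unidentifiable rather than failed.

## Divergence dating

The topology is fixed; only node ages, clock parameters and (optionally)
substitution parameters are sampled. This is the main simplification
relative to a full BEAST analysis and is deliberate: the analyses this
package supports use a topology already established by separate
phylogenetic runs. The sampler is Metropolis-within-Gibbs: uniform-window
moves on internal node ages within their (oldest child, parent) interval,
a multiplicative move on the root height above its oldest child, and
scale moves on the clock mean rate, per-branch rates and the lognormal
spread parameter. A "generation" is one elementary proposal.

The Yule prior is used in its form conditioned on the root age and tip
count: the joint density of the remaining node ages is proportional to
exp(−λ · total tree duration) (derivable from the pure-birth process by
noting the lineage-count factors are fixed given n). This makes
prior-only runs directly checkable against forward rejection-sampling of
the pure-birth process, which the test suite does. The birth rate λ is a
fixed configuration value (default 0.05/My). Calibrations are normal
priors on clade MRCA ages (default sd 5% of the mean when unstated); at
least one is required, since node ages are otherwise unidentifiable. The
clock rate prior is normal (default mean 0.1, the convention for these
data) in substitutions/site per My — the time unit is whatever unit the
calibrations use, and the rate prior must be chosen in the same unit; it
is deliberately exposed as configuration because published descriptions
often leave the unit implicit.

Chain defaults are desk-scale (tens of thousands of proposals, thinning
100) — a deliberately scaled-down stand-in for production runs of tens of
millions of generations, which are a configuration change, not a code
change. ESS is estimated by the autocorrelation-based (rank-normalised
bulk) estimator from ArviZ, and 95% HPD intervals are shortest intervals;
an ESS ≥ 500 gate mirrors standard practice and degenerate (constant)
traces are flagged rather than summarised. Independent chains can be
pooled with `combine_traces` after discarding a burn-in fraction
(default 25%).

The SRD06-style partition split — (1st+2nd) vs 3rd codon positions with
independent rates on a shared tree — is provided by
`partition_alignment` plus a per-partition ML rate multiplier.

## What the synthetic data do and do not establish

The generators emulate the architecture and the generative models the
estimators assume (GY94 mixtures, GTR+Γ clock trees, planted event
counts), so passing tests establish internal correctness and calibration:
exact likelihoods against enumeration, parameter recovery, type-I error
control, HPD coverage. They do not establish robustness to the ways real
mitogenomes violate these models — among-site compositional
heterogeneity, strand-asymmetric mutation, alignment error in diverged
non-coding regions, saturation on deep branches — and the published
per-species identity values additionally depend on unstated aligner
parameters of the original analysis, which is why they are treated as
pattern-level references rather than reproduction targets.

## Experiment sizes

The replicated validation experiments are sized for a single CPU: the
pruning/enumeration oracle uses 200 random instances of ≤4 taxa and ≤3
sites; ω recovery uses 5000 codons on a 4-taxon tree; the LRT type-I rate
uses 100 null replicates of 200 codons with single-start fits; clock HPD
coverage uses 20 replicates of 1000 sites with 20,000-proposal chains;
the ESS calibration uses an AR(1) chain of 20,000 samples with ρ=0.9.
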