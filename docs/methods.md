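# Methods

`ssrdem` implements the population-genetic analysis chain used to
characterize large codominant-marker (SSR/microsatellite) germplasm panels:
diversity and differentiation statistics, Bayesian admixture clustering with
model-choice diagnostics, heterozygosity-excess bottleneck tests, coalescent
ABC inference of demographic change, and allele-coverage core-collection
selection.  This note records the models, the parameters that matter, and
the numerical choices made where the design was genuinely open.

## Data model

A `GenotypeMatrix` holds diploid calls (unordered pairs of positive integer
allele codes — fragment sizes in bp or repeat counts) for `n` individuals at
`L` loci, with one canonical missing marker; dialect-specific encodings
(GenePop `000`, STRUCTURE `-9`, CSV empty/`NA`) are translated at the parse
boundary, so every downstream module sees a single validated representation.
Allele codes are treated as abstract labels by the diversity and
differentiation statistics (which are label-invariant) and as sizes on a
repeat-number lattice only where step distances matter (bottleneck mutation
models, ABC summary statistics).

## Diversity statistics

Per locus, from non-missing calls only: observed allele number N_A;
effective allele number N_E = 1/Σp²; Shannon index I = −Σp ln p; observed
heterozygosity H_O; unbiased gene diversity H_E = 2n/(2n−1)·(1−Σp²).
Allelic richness A_R uses hypergeometric rarefaction over gene copies,
A_R(g) = Σ_a [1 − C(2n−n_a, g)/C(2n, g)]; the default rarefaction size is
the smallest non-missing copy count over group × locus cells, so groups of
unequal size are comparable.  F_IS is the Weir & Cockerham (1984)
single-population variance-component estimator; the multilocus value pools
components over loci (a mean of per-locus ratios is also reported — the two
differ when locus information is unbalanced, and component pooling is the
default because it matches how the per-locus estimator itself is built).
Significance is a one-sided permutation test toward heterozygote deficit:
gene copies are shuffled among individuals within each locus (B = 1000 by
default, seedable), which preserves allele frequencies while enforcing
random mating.

Null-allele frequency uses the closed-form Brookfield-1 estimator
r = (H_E − H_O)/(1 + H_E), floored at 0.  This is a deliberately rough
screen: at multiallelic loci its plug-in expectation is well below the true
null frequency (e.g. ≈ 0.15 for a 0.3-frequency null behind two visible
alleles), so it should be read as a deficit indicator, not an unbiased
estimate.

## Differentiation

F_ST is the multi-allele Weir & Cockerham θ with variance components a, b,
c summed over alleles and loci; pairwise values permute individuals between
the two groups for significance.  Nei's distance is offered as the 1972
standard form (default) and the 1978 sample-size-unbiased form, since
published tables rarely say which was used.

AMOVA is distance-based at the gene-copy level: the inter-copy distance is
a 0/1 allele mismatch per locus, sums of squares reduce to allele-count
expressions, and per-locus variance components are summed over loci before
forming Φ_ST and the percentage decomposition.  Operating on gene copies
(total df on the 2N−1 scale) rather than on whole-individual allele-count
vectors keeps Φ_ST on the same scale as θ — individual-level squared
Euclidean distances weight the among-group mean-shift more heavily and
systematically inflate the among-group percentage.  Negative among-group
components are truncated to 0 before percentages.  Permutation of whole
individuals among groups gives the Φ_ST p-value.

Individual-level geometry uses the simple-matching dissimilarity
(1 − shared alleles/2, averaged over loci non-missing in both individuals),
neighbor-joining trees (scikit-bio's Saitou–Nei implementation) with
bootstrap over loci (resampled loci, recomputed distances, bipartition
support), and classical PCoA (double-centered −d²/2; negative eigenvalues
are reported, not corrected).

## Admixture model

The clustering model is the standard admixture model: individual i has
membership vector q_i over K clusters (symmetric Dirichlet(α) prior, one α
shared across clusters, uniform(0, 10) hyperprior); each allele copy picks
an origin cluster from q_i, then an allele from that cluster's locus
frequencies p_kl (Dirichlet(λ=1) prior, or an F-model prior around the
empirical frequencies with one drift parameter per cluster in the
correlated-frequency variant).  The Gibbs sampler alternates origins,
frequencies, memberships, and a Metropolis step on α (normal proposal,
σ = 0.25); missing calls contribute nothing.  Reported Q and P are
posterior means over thinned post-burn-in sweeps; the model evidence proxy
is mean(lnL) − var(lnL)/2.  The independent-frequency model is the default
for desk-scale runs (faster mixing; the correlated model is retained as an
option).  Chains of 10⁵ burn-in / 10⁶ iterations are the documented
full-scale setting; the package's defaults are desk-scale (hundreds to
thousands of sweeps), which recover well-separated structure — on the
builtin worldwide preset a (300, 1500) chain already attains a mean
absolute Q error ≈ 0.02 at K = 5.

K diagnostics: the Evanno ΔK = |L(K−1) − 2L(K) + L(K+1)|/s(K) over
replicate runs, and the similarity H′ of label-aligned runs.  Replicate
alignment resolves label switching by permuting columns against a growing
mean reference; each pairwise alignment uses the Hungarian assignment on
column cross-products, which is exact for the Frobenius objective (a greedy
search over random column orders, as in CLUMPP, is a strictly weaker search
for the same criterion); several random run orders are still tried for the
reference-growing pass.  Similarity is S(Q, Q′) = 1 − ‖Q−Q′‖_F/√(2n),
bounded in [0, 1] and 1 iff equal.  Assignment uses the inclusive
membership threshold q ≥ 0.8; below it an individual is "admixed".  Ties in
argmax break to the lowest cluster index.

## Heterozygosity-excess bottleneck test

A recently crashed population loses rare alleles faster than gene
diversity, so H_e exceeds the equilibrium H_eq expected for its observed
allele count k.  H_eq is simulated per locus: a constant-size Kingman
coalescent of the locus's n gene copies, Poisson mutations on branches
(rate tuned by bisection so the expected allele count matches k — closed
form via Ewens's formula under IAM, Monte-Carlo bisection under SMM/TPM),
and rejection until the realized allele count equals k.  Allele identity
follows the mutation model: IAM (every mutation new), SMM (±1 repeat), TPM
(single step with probability p_single = 0.95, else a ± geometric multi-step
whose variance is 12, giving geometric parameter 0.25).  Draws are cached
by (n, k, model, TPM parameters) with a key-derived sub-seed, so results do
not depend on evaluation order.

Conditional on k, H_eq is lower under IAM than under SMM/TPM (size
homoplasy: an SMM population needs more underlying diversity to display k
distinct sizes), which is why the IAM variant flags excess most readily.

Aggregation is the one-tailed Wilcoxon signed-rank test toward excess on
per-locus differences H_e − median(H_eq).  Median centering is a
calibration choice: H_e | k is left-skewed, so centering at the mean puts
more than half of the null mass above zero and inflates the one-tailed
rejection rate severalfold (measured ≈ 0.35 at α = 0.05 versus ≈ 0.07 with
median centering under an SMM null).  The exact signed-rank null is used up
to 25 loci (no ties), the continuity-corrected normal approximation above.
The qualitative mode-shift test pools within-group allele frequencies into
ten classes of width 0.1 and reports "shifted" when the modal class is not
the rarest class.

Calibration studies in the test suite use θ_past = 4Nμ = 5 (a typical
diverse SSR panel), and the power study a 100-fold crash 0.25 × 2N_present
generations before sampling — inside the transient window in which the
excess signal exists before the population re-equilibrates.

## Coalescent ABC

The demographic model is a rooted five-population tree (clusters 1+2
sister; 3+5 sister; 4 basal to (3,5)) with one size change per sampled
population — the target parameter is r = N_present/N_past on a log10 scale
— plus admixture pulses (lineage reassignment with probability a at the
pulse time) mirroring three historical contacts, including basal/ancestral
introgression into the Central-Asian cluster via an unsampled ghost lineage
that persists from the present to the root.  Coalescent simulation and the
generalized stepwise mutation model (95% single-step) come from msprime;
each locus is an independent 1-site tree.

Summary statistics (40 for five populations): per population, mean allele
number, mean unbiased gene diversity, mean allele-size variance, and the
mean M-index (alleles per unit of allele-size range); per pair,
Weir–Cockerham F_ST and a shared-allele distance 1 − Σ_a min(p₁a, p₂a)
averaged over loci.

Inference is rejection ABC: priors log10(r) ~ U(−2, 2) and a ~ U(0, 1);
statistics normalized by their simulated standard deviation (zero-variance
or undefined statistics dropped with a warning); Euclidean distance;
closest fraction accepted; optional local-linear regression adjustment with
Epanechnikov weights.  The regression uses the leading principal components
of the normalized statistics (at most 15, and at most a quarter of the
accepted count) — regressing on all ~40 raw statistics with a comparable
number of accepted draws interpolates and collapses the posterior.
Adjusted proportions are clipped to [0, 1] and adjusted log-ratios to the
prior box.  Posterior modes come from a Gaussian KDE on a 512-point grid;
classification uses the mode with a ±0.25 dead zone (stable) and flags a
parameter uninformative when the prior–posterior total-variation distance
falls below 0.1.

Desk-scale settings (hundreds of simulations, ~10 loci, ~12 diploids per
population) recover the direction and rough magnitude of a 10-fold size
change and strong admixture; they do not deliver the tight posteriors of
full-scale runs with tens of thousands of simulations.

## Core collection

The maximization strategy treats each (locus, allele) pair as a class and
greedily adds the accession covering the most uncovered classes; ties break
to the more heterozygous accession, then the lower input index; selection
stops at full coverage, and a pruning pass removes accessions whose classes
are covered by the rest.  Missing calls contribute no classes, so coverage
is of observed alleles.  The procedure is deterministic, always attains
100% coverage, and on small instances where the optimum is computable it
matches the exhaustive minimum cover most of the time (greedy set cover
carries the usual 1 + ln(max classes per accession) guarantee).

## Synthetic panels

The generator mirrors the admixture model it is meant to test: cluster
frequencies are F-model draws, Dirichlet(p_anc·(1−F)/F), so each cluster's
drift parameter F sits on the F_ST scale; genotypes are drawn copy-wise
through each individual's admixture row, making within-cluster genotypes
Hardy–Weinberg in expectation; missing data are per-call independent
Bernoulli; an optional null allele (the allele nearest frequency 0.3)
silences its homozygotes and hides heterozygotes.

`worldwide_preset` emulates a worldwide apricot germplasm panel: 890
accessions in 7 geographic groups (67, 142, 86, 86, 250, 214, 45), 25 loci
with 18–32 ancestral alleles, 5 latent clusters with drift parameters
(0.13, 0.05, 0.15, 0.42, 0.17) chosen so the realized among-cluster θ on
assigned individuals lands near 0.17, ~31% admixed individuals (maximum
membership < 0.8; 60% in the America group), and group→cluster composition
following the panel's geography (East Asia→1, Central Asia→2,
Irano-Caucasian→3 with part of North Africa, Continental Europe→4,
Mediterranean Europe→5 with the rest of North Africa; America a 5/2
mixture).  Admixture partners follow the panel's contact zones — with
uniformly random partners the heavily admixed America group would exceed
Central Asia in gene diversity, contradicting the structure the preset
must emulate.  What the preset does *not* model: linkage between loci,
mutation during forward sampling, genotyping error beyond nulls, pedigree
or clonal structure, and within-group spatial substructure.  Tests passing
on it therefore validate estimator correctness and recovery under the
assumed model, not robustness to those real-data complications.

## Pipeline

`run_pipeline` chains the stages from one config with one explicit seed per
stochastic stage (validation fails before any computation if one is
missing).  Consensus cluster labels at the selected K (ΔK argmax among
interior K unless pinned) feed the per-cluster statistics, bottleneck tests
and ABC stage, with "admixed" individuals excluded from per-cluster
statistics.  Every output table records a config hash; identical configs
reproduce outputs byte-for-byte.

## Known limitations

- The H_eq simulator conditions on k with a θ tuned to E[k] = k; the
  resulting conditional distribution is slightly biased at extreme k
  (visible as the residual ~0.07 type-I rate at nominal 0.05).
- Brookfield-1 underestimates null frequencies at multiallelic loci (see
  above).
- The ABC scenario fixes topology and event times; only size ratios and
  pulse proportions are inferred, and absolute times are deliberately out
  of scope.
- The admixture sampler reports within-run posterior means; in weakly
  separated data, within-chain label switching would blur Q (replicate
  alignment handles between-run switching only).
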