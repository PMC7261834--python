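# ssrdem

Population-genetic analysis of codominant microsatellite (SSR) germplasm
panels: diversity and differentiation statistics, Bayesian admixture
clustering with model-choice diagnostics, heterozygosity-excess bottleneck
tests, coalescent-ABC demographic inference, and allele-coverage core
collections — plus a forward simulator of admixed SSR panels for
validation.  Written for curators and population geneticists working with
genebank collections genotyped at multiallelic codominant markers.

## What it computes

- **Diversity** (per locus / per group): N_A, N_E = 1/Σp², Shannon's I,
  H_O, unbiased H_E, rarefied allelic richness A_R (hypergeometric, gene
  copies), private and unique alleles, Weir–Cockerham F_IS with a
  permutation test toward heterozygote deficit, and the Brookfield
  null-allele estimate (H_E − H_O)/(1 + H_E).
- **Differentiation**: pairwise and global Weir–Cockerham θ with
  permutation p-values, Nei's genetic distance (1972 standard / 1978
  unbiased), two-level distance AMOVA (Φ_ST), simple-matching
  dissimilarity, neighbor-joining trees with bootstrap over loci, PCoA.
- **Structure**: an admixture-model Gibbs sampler (STRUCTURE-style; Q, P,
  α), Evanno's ΔK, CLUMPP-style run alignment with similarity H′, and
  threshold assignment (q ≥ 0.8, else "admixed").
- **Bottleneck**: per-locus equilibrium heterozygosity H_eq simulated by a
  conditional coalescent under IAM / SMM / TPM (95% single-step, multi-step
  variance 12), one-tailed Wilcoxon signed-rank aggregation, and the
  allele-frequency mode-shift test.
- **Demography**: rejection ABC over a five-population scenario with
  admixture pulses; per-cluster size ratios r = N_present/N_past on
  log10 scale (peak < 0: bottleneck; ≈ 0: stable; > 0: expansion) and pulse
  proportions, with local-linear adjustment.
- **Core collection**: greedy maximization of allele-class coverage with
  redundancy pruning; always captures 100% of observed alleles.

See `docs/methods.md` for the models, estimators and numerical choices.

## Worked example

```python
import numpy as np
from ssrdem.synthetic import worldwide_preset
from ssrdem.diversity import locus_summary
from ssrdem.differentiation import amova, global_fst
from ssrdem.io_formats import Partition
from ssrdem.core_collection import build_core, coverage_report

# synthetic stand-in for a worldwide 890-accession, 25-marker panel
g, geo, true_q, clusters = worldwide_preset(seed=1)

per_locus, multilocus = locus_summary(g, rarefaction_g=None)
print(f"mean N_A = {multilocus['N_A']:.2f}, H_O = {multilocus['H_O']:.3f}, "
      f"H_E = {multilocus['H_E']:.3f}, F_IS = {multilocus['F_IS']:.3f}")

lab = np.argmax(true_q, axis=1)
assigned = np.flatnonzero(true_q.max(axis=1) >= 0.8)
p5 = Partition({g.individuals[i]: f"c{lab[i] + 1}" for i in assigned})
print(f"global theta over 5 clusters = {global_fst(g, p5):.3f}")
print(f"AMOVA among clusters = {amova(g, p5).table.loc['among_groups', 'pct']:.1f}%")

core = build_core(g)
rep = coverage_report(g, core)
print(f"core: {rep['n_core']}/{rep['n_panel']} accessions, "
      f"coverage {rep['coverage']:.0%}")
```

prints

```
mean N_A = 21.60, H_O = 0.795, H_E = 0.892, F_IS = 0.109
global theta over 5 clusters = 0.176
AMOVA among clusters = 17.6%
core: 82/890 accessions, coverage 100%
```

— the five latent clusters of the simulated panel are strongly
differentiated (θ ≈ 0.18; ~18% of molecular variance among clusters), the
pooled panel shows the heterozygote deficit expected under such structure
(Wahlund effect: F_IS ≈ 0.11), and a core of under 10% of accessions
already captures every observed allele (real panels, with rarer alleles
and genotyping noise, need considerably larger cores).

A command-line interface mirrors the library
(`ssrdem simulate | convert | diversity | diff | structure | bottleneck |
abc | core | run`); `ssrdem run --config pipeline.yaml` executes the full
chain with per-stage seeds and byte-reproducible outputs.

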