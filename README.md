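# msatpipe

Sequencing-based microsatellite genotyping and population-genetic analysis.

Microsatellites (short tandem repeats, STRs) are classically genotyped by
fragment length, which hides *homoplasy*: alleles of equal length but
different sequence. Amplicon sequencing resolves this — but turns allele
calling into a read-filtering problem: PCR stutter (reads one repeat unit
off), point errors, and wildly uneven per-amplicon depth all masquerade as
alleles. `msatpipe` implements the full path from pooled, inline-barcoded
amplicon reads to population-genetic inference, for study designs such as
reef-coral connectivity surveys (multiple sites per island, tens of diploid
colonies per site, 10–20 loci):

* **Demultiplexing & trimming** — reads structured
  `siteTag + colonyTag + FWDprimer + flank + (motif)ᵏ + flank + RVSprimer`
  are assigned by exact tags and a mismatch-tolerant primer match, then
  reverse-primer- and quality-trimmed.
* **Collapse & filters** — identical inserts are collapsed into unique
  sequences with depths; filters remove sequences < 15 bp or above the
  locus's longest known allele + 4 repeats, with pooled depth < 10 reads,
  or present in < 2 colonies.
* **Allele calling (half-max rule)** — per colony-locus, keep the deepest
  sequence and every sequence with depth > half of it; one candidate =
  homozygote, two = heterozygote; more than two are resolved by depth or at
  random (replicated 10×). Genotypes are encoded by **repeat-region
  length** (the sequencing analogue of peak calling; an etandem-style
  scanner separates the STR from its flanks) or by **unique sequence ID**.
* **Population genetics** — Nei–Chesser diversity (H_O, H_S, H_T, H′_T),
  Hedrick's G′_ST and Jost's D; Weir–Cockerham (1984) AMOVA variance
  components giving F_ST and F_IS with permutation tests; Meirmans-
  standardized F′_ST = F_ST / F_ST(max) via population-specific allele
  recoding; Monte-Carlo exact tests of differentiation; rarefied allelic
  richness.
* **Bottleneck tests** — Cornuet–Luikart heterozygosity excess under the
  infinite-allele (IAM) and two-phase (TPM, 70% single-step) mutation
  models, with coalescent-simulated H_eq conditioned on the observed allele
  count, a one-tailed Wilcoxon signed-rank test across loci, and the
  L-shape / mode-shift graphical test.
* **Ordination** — covariance PCA of individuals (allele-indicator counts)
  and of populations (allele frequencies), with permutation axis tests.
* **Synthetic data** — a generator that emulates the whole study design
  (island-model frequencies at a target F_ST via Balding–Nichols sampling,
  Hardy–Weinberg genotypes, negative-binomial depth, Beta allele balance,
  ±1-repeat stutter, point errors, low-quality tails) and ships truth
  tables, so every stage is testable end-to-end without any real reads.

## Worked example

```python
import numpy as np
import msatpipe as mp
from msatpipe import popgen

config = mp.SimConfig(seed=3)              # 7 sites, 3 islands, 11 loci
truth  = mp.simulate_truth(config)
matrix = mp.truth_genotype_matrix(truth, islands=config.islands)

div = popgen.diversity_indices(matrix)
res = popgen.standardized_fst(matrix, permutations=999,
                              rng=np.random.default_rng(1))
```

prints (via `python examples/diversity_and_fst.py`):

```
loci: 11, mean alleles/locus N = 10.27, effective NE = 4.51
HO = 0.724  HE(HS) = 0.730  H'T = 0.763  G'ST = 0.152
FST = 0.0406 (p = 0.001)   F'ST = 0.1507   FIS = 0.0079
truth-frequency oracle F'ST = 0.1530
F'ST Palau-Yap: 0.051 (p = 0.002)
F'ST Palau-Ngulu: 0.096 (p = 0.002)
F'ST Yap-Ngulu: 0.085 (p = 0.002)
```

F_ST is small (0.04) because within-population heterozygosity is high;
F′_ST rescales it by its maximum given that diversity (here ≈ 0.15,
closely matching the value implied by the true simulated frequencies).
Pairwise island values are of the same order as the global value —
structure at every scale. On true genotypes F_IS ≈ 0, as it should be
under Hardy–Weinberg sampling; genotypes called from noisy reads show a
heterozygote deficit (allele dropout), which the dataset-comparison stage
quantifies.

The `examples/` directory has one short script per capability
(`simulate_library`, `genotype_library`, `diversity_and_fst`,
`bottleneck_test`, `pca_ordination`, `full_pipeline`). A thin CLI wraps the
orchestration layer:

```bash
msatpipe all -c run.yaml          # simulate/ingest → genotype → analyse
msatpipe genotype -c run.yaml     # stop after genotype tables
```

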