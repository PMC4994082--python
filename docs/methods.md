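# Methods

This note records the models, estimators, numerical conventions and design
choices behind `msatpipe`, and what the synthetic-data validation does and
does not demonstrate.

## Amplicon model and genotyping stages

A sequenced microsatellite amplicon is modelled as

    siteTag · colonyTag · fwd_primer · left_flank · motif^k · right_flank · rvs_primer

with reads assumed already merged (paired-end merging is upstream; a naive
overlap merger is provided as convenience plumbing only).

**Demultiplexing.** Site and colony tags are matched exactly; the forward
primer tolerates up to `max_mismatch` substitutions (default 2, no indels),
ties resolved by fewest mismatches and ambiguous ties left unassigned.
Rationale: the 5-nt tags come from a distance-2 code, so a single
substitution cannot convert one tag into another but also cannot be
corrected; primers are 20-mers pairwise ≥ 6 apart, so two substitutions are
unambiguous. Assigned + unassigned always equals the input count.

**Trimming.** The reverse primer (found exactly or within `max_mismatch`)
and everything after it is removed, then the read is truncated at the first
sliding window (default width 4) whose mean Phred score falls below 15.
Trimming is idempotent. Fully trimmed reads survive as zero-length inserts
and die in the length filter, keeping the read accounting exact.

**Collapse and filters.** Identical inserts are collapsed exactly (no fuzzy
clustering); depth = multiplicity. Filters, in order:

1. length: keep `15 ≤ len ≤ 190`, and per locus at most the longest known
   allele + 4 repeat units (both caps applied; the global and per-locus
   bounds are separately configurable because their precedence is a
   genuinely open choice);
2. pooled depth: pooling per locus across the entire dataset, drop
   sequences with pooled depth < 10;
3. prevalence: drop sequences present in < 2 colonies regardless of depth
   (raising this floor to 11 reproduces the stricter "min10" dataset
   variants).

Boundary semantics are literal: "fewer than 10" keeps depth ≥ 10, "less
than two colonies" keeps ≥ 2. Every rejected sequence is written to an
audit table with its reason — the programmatic version of inspecting the
reject file by eye.

**Allele calling.** Within a colony-locus, candidates are the top-depth
sequence plus every sequence with depth **strictly** greater than half the
top depth ("greater than half" read literally). One candidate =
homozygote; two = heterozygote. With more than two, the second allele is
chosen either by depth (next-highest; ties among the second rank broken
uniformly at random) or uniformly at random among all non-top candidates.
The random strategy is replicated k = 10 times with independent child
seeds; replicate 0 is the canonical analysis dataset. The top allele is
excluded from the random pool — it is always allele 1.

**STR/flank separation.** An etandem-style scanner tries every motif size
2–6 bp and offset, scoring +1/−1 against the run's periodic consensus, and
keeps the maximal-score run. Three conventions beyond the basic rule were
needed to make detection exact on constructed inserts: runs are trimmed to
whole motif copies; a run must contain at least two *exact* adjacent
copies (otherwise mismatch tolerance finds a degenerate "repeat" in almost
any sequence); and score ties prefer fewer mismatches, then more copies of
a shorter motif (a compound 2m-mer always ties the score of the primitive
m-mer it contains). Locus flanks in the generator are validated against
round-trip recovery, so on error-free sequence the decomposition is exact.

**Encoding.** `length` labels an allele by its repeat-region length
(same-length alleles merge, as in fragment analysis — homoplasy by
construction); `unique_id` assigns one integer per distinct sequence.
Consequently the unique-ID allele count per locus is always ≥ the length
allele count. A sequence with no detectable repeat cannot be
length-encoded; the call becomes missing and is logged.

## Population-genetic estimators

Missing genotypes are handled by pairwise deletion throughout. Before
analysis, loci with ≥ 15% missing data and then individuals with ≥ 35%
missing (over retained loci) are dropped.

**Diversity (Nei–Chesser small-sample estimators)** with ñ the harmonic
mean of per-population sample sizes and r populations:

    H_S = (ñ/(ñ−1)) · (1 − mean_pops Σ_k p_k² − H_O/(2ñ))
    H_T = 1 − Σ_k p̄_k² + H_S/(ñ·r)
    G_ST = (H_T − H_S)/H_T
    G′_ST = G_ST (r−1+H_S) / ((r−1)(1−H_S))        (Hedrick)
    H′_T = H_S + (H_T − H_S)·r/(r−1)
    D = (r/(r−1)) (H_T − H_S)/(1−H_S)              (Jost)
    N_E = 1/Σ_k p̄_k²

Multilocus H-values are unweighted locus means; multilocus ratio statistics
are computed from the averaged H_S and H_T, with monomorphic loci excluded
and flagged. These sample-size-corrected estimators can be slightly
negative for identical small samples; that is expected behavior, not a
bug. The "N" column of the dataset-comparison table is the mean number of
alleles per locus (pooled over populations), and N_E the effective number
of alleles — allele counts, not individual counts.

**F-statistics.** Weir & Cockerham (1984) per-allele variance components a
(among populations), b (among individuals within populations) and c
(within individuals), summed over alleles and loci: F_ST = Σa/Σ(a+b+c),
F_IS = Σb/Σ(b+c). This is a method-of-moments variance decomposition of
the same family as AMOVA; exact numerical parity with any particular AMOVA
program is not claimed. Significance: F_ST permutes individuals among
populations; F_IS permutes allele copies among individuals within each
population; p = (#{perm ≥ obs}+1)/(n+1).

**Standardized F′_ST (Meirmans).** F′_ST = F_ST / F_ST(max), where
F_ST(max) is the same estimator applied to a recoded matrix whose allele
labels are made population-specific (identical within-population genotype
structure, zero sharing). Its p-value is inherited from the F_ST
permutation test. When no locus is polymorphic F_ST is 0/0; this is raised
as an explicit error (note the recoded F_ST(max) is 1, not 0, in that
case — the undefined quantity is the numerator).

**Exact tests.** Per population pair and locus, the alleles × populations
contingency table is compared against `steps` Monte-Carlo samples from the
conditional null (multivariate hypergeometric with fixed margins); the
p-value is the add-one-corrected fraction of sampled tables whose
conditional probability is ≤ the observed table's. This replaces the
classical dememorized Markov chain; `steps` plays the role of the chain
length. Loci combine per pair by Fisher's method (χ² with 2L d.f.); the
add-one correction also keeps log p finite.

**Allelic richness.** Rarefaction to g = 2 × 24 gene copies by default:
AR = Σ_i [1 − C(N−N_i, g)/C(N, g)], computed in log-Γ space. Samples with
N < g are flagged NaN, never extrapolated.

## Bottleneck tests

Per polymorphic locus the observed heterozygosity is Nei's unbiased
estimator, He = (n/(n−1))(1 − Σ p̂²). The equilibrium distribution H_eq
conditional on the observed allele count k uses coalescent simulations of
the same number of gene copies: θ is calibrated so the mean simulated
allele count equals k (closed-form Ewens expectation Σθ/(θ+i) with
bisection for the IAM; Monte-Carlo bisection for the TPM), and only
simulations yielding exactly k alleles are retained. Simulated H_eq gets
the **same** n/(n−1) correction as the observed value — comparing a
corrected observable against an uncorrected null is systematically biased
toward "excess".

IAM samples come from the Hoppe-urn representation of the coalescent
(exact for the Ewens sampling distribution, O(n) per sample, vectorized
across simulations). TPM samples use explicit Kingman genealogies with
Poisson(θ·branch/2) mutations; each mutation steps ±1 repeat with
probability 0.70, otherwise ±geometric with variance 30 (the conventional
default; only the 70/30 split is prescribed, the multistep variance is
surfaced in `MutationModel`). For the IAM, conditioning on k makes θ
irrelevant (k is sufficient), so the calibration matters only for the TPM.

The population-level test is a one-tailed Wilcoxon signed-rank on the
per-locus differences He − mean(H_eq); with all 11 loci in excess the
exact p is 2⁻¹¹ ≈ 0.000488. **Calibration caveat:** conditional on k the
distribution of He is left-skewed, so the signed-rank symmetry assumption
fails in proportion to that skew. Measured on equilibrium IAM populations
(n = 30 diploids, 11 loci): at modest diversity (θ = 1, ~4–6 alleles per
locus) the empirical type-I error at α = 0.05 is ≈ 0.05; at high diversity
(θ = 2–5, He ≈ 0.7) it rises to ≈ 0.10 whether raw or standardized
differences are ranked. This is inherent to the test construction, not an
implementation artifact (conditional on k, observed and simulated samples
are exchangeable by the Ewens sufficiency argument). Interpret rejections
at high-diversity loci accordingly.

The mode-shift test bins all allele frequencies of a population into ten
left-open classes (0,0.1], …, (0.9,1]; boundary values fall in the lower
bin. "L-shaped" requires the first class to hold strictly more alleles
than every other class. Note that the island-model generator draws
frequencies from Dirichlet distributions, not from a coalescent
equilibrium, so bottleneck statistics computed on its output can flag
heterozygosity excess even though no bottleneck was simulated; calibration
claims are made only on coalescent equilibrium populations
(`equilibrium_population`), and bottleneck power on `founder_reduction`
(Wright–Fisher reduction and drift, no new mutation).

## Ordination

Individuals are embedded as allele-indicator count vectors (0/1/2 per
allele), missing genotypes mean-imputed per column; populations as
allele-frequency vectors. Both use column-centered covariance PCA (SVD).
Axis sign is fixed by making the largest-magnitude loading positive. Axis
significance shuffles each column independently and compares eigenvalues
rank-for-rank — a documented choice; other permutation schemes exist and
give different absolute p-values.

## Synthetic-data generator

The generator's defaults emulate the target study design: seven sites on
three island groups with 48/48/48/37/48/48/43 diploid colonies, eleven
loci (di- to tetranucleotide motifs, validated flanks, inserts ≤ 190 bp),
and island-model differentiation. Parameters, with units and rationale:

| parameter | default | meaning / rationale |
|---|---|---|
| `theta_fst` | 0.04 | Balding–Nichols divergence; matches the global F_ST scale of the emulated design |
| `ancestral_dirichlet` | 0.6 | skewed (L-shaped) ancestral frequency spectra; yields H_S ≈ 0.65–0.73 |
| ancestral alleles/locus | 4–12 | typical microsatellite panels |
| `mean_depth` | 50 reads | per colony-locus; amplicon depth is a convention (unreported in the emulated study) |
| `depth_dispersion` | 0.7 | NB shape; strong skew, ≈ 5% zero-coverage dropouts (realistic missingness) |
| `allele_balance_beta` | 5 | Beta(5,5) amplification balance; produces a heterozygote deficit (allele dropout under the half-max rule) comparable to real amplicon data |
| `stutter_rate` | 0.10/read | ±1 repeat unit, direction equiprobable, floor at one copy |
| `error_rate` | 0.001/base | uniform substitutions |
| `flank_snp_prob` | 0.25 | fraction of alleles duplicated as same-length flank variants, to exercise length-vs-ID encoding |
| `lowq_tail_frac` | 0.10 | reads given a corrupted low-quality tail, to exercise the trimmer |

Reads are split between a heterozygote's alleles as round(share × depth)
with share ~ Beta(b, b) — the Beta draw *is* the realized balance. This
matters: an additional binomial sampling layer would make perfectly
balanced heterozygotes fail the strict half-max rule through counting
noise alone, and ideal libraries would not be exactly recoverable.

`SimConfig.noise_free()` switches off every noise channel (stutter, error,
quality tails), tightens balance (Beta(500,500)) and evens depth, and sets
`ensure_min_prevalence=2`, which redraws genotypes of colonies carrying a
globally-singleton allele. Singleton alleles are otherwise removed —
correctly — by the prevalence filter, so exact recovery is only a coherent
target without them. The preset exists to validate that the genotyping
stages are exact when sequencing is; it is not a realistic library.

**What passing tests show, and what they do not.** The noise-free
round-trip shows the deterministic stages (demux, trim, collapse, filters,
half-max calling, STR splitting, encoding) are exact. The estimator-
recovery checks show the F′_ST machinery recovers the differentiation
implied by the true frequencies (mean absolute error ≈ 0.001–0.003 at the
study scale, against a closed-form infinite-sample oracle). None of this
shows the noise model captures real amplicon chemistry: per-read
independent stutter and uniform point errors, with chimerism and somatic
variation deliberately out of scope, generate far fewer multi-allele
(> 2 candidate) colonies than real libraries show, and the artifact
alleles they do generate echo locally common alleles rather than being
shared across populations. In particular, the direction of the small
F_ST/F′_ST shift between depth-based and random second-allele selection is
not structurally determined under this noise model (measured differences
~10⁻⁴ with unstable sign), even though the heterozygote-deficit and
allele-count effects of the encodings reproduce cleanly.

## Orchestration and reproducibility

`RunConfig` carries every threshold with its canonical default (15/190 bp,
+4 repeats, depth 10, 2 colonies, 15%/35% missing, 24 rarefaction
colonies, 20 000 AMOVA permutations, 100 000 exact-test steps, 10 000
bottleneck iterations and PCA permutations, 10 replicates); a config file
missing any of them fails validation by name. One master seed derives
per-stage child seeds (CRC32 of the stage name into a SeedSequence), so
stages are independently re-runnable and a bundle reproduces
byte-for-byte. Tests and the acceptance script run the same machinery at
reduced problem sizes (hundreds of permutations, 400–1000 bottleneck
iterations, one TPM site) — chosen as the package's own default validation
scale; all counts are configurable upward.

## Known limitations

- No fuzzy read collapse, no chimera/somatic-mosaicism model, no
  paired-end merge statistics, no three-level (island > site) AMOVA, no
  SMM-only bottleneck model, no clustering analyses — all deliberate
  scope cuts.
- The Wilcoxon heterozygosity-excess test is anti-conservative at high
  diversity (see above).
- Genepop output is limited to 3-digit allele codes (≤ 999 labels per
  locus, enforced).
- The pipeline reads locus/barcode metadata from the built-in defaults
  when simulating; supplying external locus tables is supported at the
  API level (`LocusSpec`, `BarcodeScheme`) but no table-file parser is
  bundled.
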