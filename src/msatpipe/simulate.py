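"""Synthetic amplicon-read libraries with known genotypes.

Simulates the full study design end-to-end: island-model allele-frequency
divergence at a target FST (Balding-Nichols Dirichlet sampling), diploid
Hardy-Weinberg genotypes per colony, and merged amplicon reads with inline
site/colony tags, primers, PCR stutter (+-1 repeat unit), per-base point
error, skewed negative-binomial depth and an optional low-quality tail.
Every library ships with truth tables, so downstream genotyping stages can
be validated read-for-read.

Allele space is simulated on repeat counts; optionally some alleles carry a
single flank substitution ("flank variants"), which produces same-length,
different-sequence alleles — the case that separates length-based from
sequence-identity genotyping.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .loci import BASES, DEFAULT_ISLANDS, DEFAULT_POP_SIZES, BarcodeScheme, LocusSpec, default_barcode_scheme, default_loci
from .strsplit import split_tandem_repeat

__all__ = [
    "Allele",
    "SimConfig",
    "TruthSet",
    "draw_pop_freqs",
    "build_allele_sequence",
    "simulate_genotypes",
    "simulate_read_set",
    "simulate_truth",
    "expected_fst",
    "expected_fprime_st",
    "truth_genotype_matrix",
    "write_fastq",
]


@dataclass(frozen=True)
class Allele:
    """One microsatellite allele: a repeat count plus a flank-variant index.

    ``variant`` 0 is the canonical flank; positive values substitute one base
    in the left flank, yielding an allele of identical length but different
    sequence.
    """

    repeats: int
    variant: int = 0


@dataclass
class SimConfig:
    """Study-design and noise parameters of the simulator.

    Defaults emulate the sampling design this package targets: seven sites
    on three islands with 37-48 diploid colonies each and eleven loci.
    Depth is negative binomial with mean ``mean_depth`` and shape
    ``depth_dispersion`` (variance m + m^2/k; the small default shape gives
    the strongly skewed per-amplicon coverage typical of pooled amplicon
    libraries, including occasional zero-coverage dropouts).
    """

    sites: list[str] = field(default_factory=lambda: list(DEFAULT_ISLANDS))
    islands: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ISLANDS))
    pop_sizes: list[int] = field(default_factory=lambda: [DEFAULT_POP_SIZES[s] for s in DEFAULT_ISLANDS])
    theta_fst: float = 0.04
    loci: list[LocusSpec] = field(default_factory=default_loci)
    mean_depth: float = 50.0
    depth_dispersion: float = 0.7
    allele_balance_beta: float = 5.0
    stutter_rate: float = 0.10
    error_rate: float = 0.001
    flank_snp_prob: float = 0.25
    lowq_tail_frac: float = 0.10
    ancestral_dirichlet: float = 0.6
    min_ancestral_alleles: int = 4
    max_ancestral_alleles: int = 12
    #: when > 0, genotypes are redrawn until every allele present in the
    #: truth is carried by at least this many colonies; the prevalence
    #: filter then cannot remove a true allele, making noise-free libraries
    #: exactly recoverable.  0 leaves private alleles in (realistic data).
    ensure_min_prevalence: int = 0
    seed: int = 0

    @property
    def n_pops(self) -> int:
        return len(self.sites)

    @classmethod
    def noise_free(cls, **overrides) -> "SimConfig":
        """An ideal library: no stutter, no point error, no low-quality
        tails, tightly balanced alleles and near-uniform depth.  Used to
        validate that the genotyping stages are exact when sequencing is."""
        base = dict(
            stutter_rate=0.0,
            error_rate=0.0,
            lowq_tail_frac=0.0,
            allele_balance_beta=500.0,
            mean_depth=40.0,
            depth_dispersion=50.0,
            ensure_min_prevalence=2,
        )
        base.update(overrides)
        return cls(**base)

    def __post_init__(self) -> None:
        # tolerate loci deserialized from YAML/JSON as plain mappings
        self.loci = [
            l
            if isinstance(l, LocusSpec)
            else LocusSpec(**{**l, "repeat_range": tuple(l["repeat_range"])})
            for l in self.loci
        ]
        if not 0 < self.theta_fst < 1:
            raise ValueError("theta_fst must be in (0, 1)")
        if not 0 <= self.stutter_rate < 1:
            raise ValueError("stutter_rate must be in [0, 1)")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0 <= self.flank_snp_prob <= 1:
            raise ValueError("flank_snp_prob must be in [0, 1]")
        if len(self.pop_sizes) != len(self.sites):
            raise ValueError("pop_sizes must match sites")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0 or self.allele_balance_beta <= 0:
            raise ValueError("depth and balance parameters must be positive")


@dataclass
class TruthSet:
    """True allele frequencies and genotypes behind a simulated library."""

    sites: list[str]
    pop_sizes: list[int]
    loci: list[LocusSpec]
    #: per locus name: list of Allele defining the column order of freqs
    alleles: dict[str, list[Allele]]
    #: per locus name: (n_pops, n_alleles) frequency matrix
    pop_allele_freqs: dict[str, np.ndarray]
    #: per locus name: (total_colonies, 2) int array of allele indices
    genotypes: dict[str, np.ndarray]
    theta_fst: float

    def __post_init__(self) -> None:
        for name, freqs in self.pop_allele_freqs.items():
            if not np.allclose(freqs.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError(f"{name}: frequencies must sum to 1 per population")

    @property
    def colony_ids(self) -> list[tuple[str, int]]:
        out = []
        for site, n in zip(self.sites, self.pop_sizes):
            out.extend((site, j) for j in range(n))
        return out

    def allele_sequence(self, locus: LocusSpec, allele: Allele) -> str:
        return build_allele_sequence(locus, allele.repeats, allele.variant)

    def to_frame(self) -> pd.DataFrame:
        """Truth table: one row per colony-locus with both allele sequences."""
        rows = []
        colonies = self.colony_ids
        by_name = {l.name: l for l in self.loci}
        for locus in self.loci:
            g = self.genotypes[locus.name]
            alleles = self.alleles[locus.name]
            for idx, (site, j) in enumerate(colonies):
                a1, a2 = alleles[g[idx, 0]], alleles[g[idx, 1]]
                rows.append(
                    {
                        "site": site,
                        "colony": f"c{j:02d}",
                        "locus": locus.name,
                        "allele1_seq": self.allele_sequence(by_name[locus.name], a1),
                        "allele2_seq": self.allele_sequence(by_name[locus.name], a2),
                        "allele1_repeats": a1.repeats,
                        "allele2_repeats": a2.repeats,
                        "allele1_variant": a1.variant,
                        "allele2_variant": a2.variant,
                    }
                )
        return pd.DataFrame(rows)


def draw_pop_freqs(
    ancestral_freqs: np.ndarray, theta: float, n_pops: int, rng: np.random.Generator
) -> np.ndarray:
    """Island-model population frequencies at a target differentiation.

    Each population's frequency vector is an independent Dirichlet draw with
    concentration ``ancestral * (1 - theta) / theta`` (the Balding-Nichols
    parameterization), so allele frequencies have expectation ``ancestral``
    and correlation ``theta`` relative to the ancestral pool.
    """
    p = np.asarray(ancestral_freqs, dtype=float)
    if not 0 < theta < 1:
        raise ValueError("theta must be in (0, 1)")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("ancestral_freqs must sum to 1")
    alpha = p * (1.0 - theta) / theta
    return rng.dirichlet(alpha, size=n_pops)


def _variant_flank(locus: LocusSpec, variant: int) -> str:
    """Left flank with one deterministic substitution per variant index."""
    if variant == 0:
        return locus.left_flank
    flank = list(locus.left_flank)
    pos = (len(flank) // 2 + (variant - 1)) % len(flank)
    orig = flank[pos]
    flank[pos] = BASES[(BASES.index(orig) + 1 + (variant - 1) // len(flank)) % 4]
    if flank[pos] == orig:  # pragma: no cover - arithmetic never yields orig
        flank[pos] = BASES[(BASES.index(orig) + 2) % 4]
    return "".join(flank)


def build_allele_sequence(locus: LocusSpec, repeats: int, variant: int = 0) -> str:
    """Insert sequence ``left_flank + motif*repeats + right_flank``."""
    lo, hi = locus.repeat_range
    if not lo <= repeats <= hi:
        raise ValueError(f"{locus.name}: repeats {repeats} outside range [{lo}, {hi}]")
    left = _variant_flank(locus, variant)
    return left + locus.motif * repeats + locus.right_flank


def _variant_ok(locus: LocusSpec, variant: int) -> bool:
    """A flank variant must not create a motif copy or disturb STR detection."""
    left = _variant_flank(locus, variant)
    if locus.motif in left:
        return False
    reps = locus.repeat_range[0]
    seq = left + locus.motif * reps + locus.right_flank
    res = split_tandem_repeat(seq)
    return res.repeat_region == locus.motif * reps and res.left_flank == left


def _ancestral_alleles(
    locus: LocusSpec, config: SimConfig, rng: np.random.Generator
) -> tuple[list[Allele], np.ndarray]:
    lo, hi = locus.repeat_range
    k = int(rng.integers(config.min_ancestral_alleles, config.max_ancestral_alleles + 1))
    k = min(k, hi - lo + 1)
    counts = rng.choice(np.arange(lo, hi + 1), size=k, replace=False)
    alleles = [Allele(int(c), 0) for c in sorted(counts)]
    extra: list[Allele] = []
    for a in alleles:
        if rng.random() < config.flank_snp_prob:
            for v in (1, 2, 3):
                if _variant_ok(locus, v):
                    extra.append(Allele(a.repeats, v))
                    break
    alleles = alleles + extra
    freqs = rng.dirichlet(np.full(len(alleles), config.ancestral_dirichlet))
    # avoid effectively-zero ancestral frequencies (invariant: every genotype
    # allele has nonzero frequency in its population)
    freqs = np.maximum(freqs, 1e-3)
    freqs /= freqs.sum()
    return alleles, freqs


def simulate_genotypes(
    truth_freqs: np.ndarray, pop_sizes: list[int], rng: np.random.Generator
) -> np.ndarray:
    """Hardy-Weinberg diploid genotypes: two independent allele draws per
    colony from its population's frequency vector, pair order randomized."""
    total = sum(pop_sizes)
    geno = np.empty((total, 2), dtype=np.int64)
    row = 0
    for pop_idx, n in enumerate(pop_sizes):
        p = truth_freqs[pop_idx]
        draws = rng.choice(len(p), size=(n, 2), p=p)
        geno[row : row + n] = draws
        row += n
    return geno


def _enforce_prevalence(
    geno: np.ndarray, freqs: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Redraw genotypes of colonies carrying an allele present in fewer than
    ``ensure_min_prevalence`` colonies, until no such allele remains."""
    pop_of = np.repeat(np.arange(len(config.pop_sizes)), config.pop_sizes)
    for _ in range(200):
        carriers: dict[int, np.ndarray] = {}
        for al in range(freqs.shape[1]):
            rows = np.nonzero((geno == al).any(axis=1))[0]
            if 0 < rows.size < config.ensure_min_prevalence:
                carriers[al] = rows
        if not carriers:
            return geno
        for rows in carriers.values():
            for r in rows:
                geno[r] = rng.choice(freqs.shape[1], size=2, p=freqs[pop_of[r]])
    raise RuntimeError("could not satisfy ensure_min_prevalence")  # pragma: no cover


def simulate_truth(config: SimConfig, rng: np.random.Generator | None = None) -> TruthSet:
    """Draw ancestral alleles, population frequencies, and genotypes."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    alleles: dict[str, list[Allele]] = {}
    freqs: dict[str, np.ndarray] = {}
    genos: dict[str, np.ndarray] = {}
    for locus in config.loci:
        a, anc = _ancestral_alleles(locus, config, rng)
        f = draw_pop_freqs(anc, config.theta_fst, config.n_pops, rng)
        f = np.maximum(f, 1e-12)
        f /= f.sum(axis=1, keepdims=True)
        alleles[locus.name] = a
        freqs[locus.name] = f
        geno = simulate_genotypes(f, config.pop_sizes, rng)
        if config.ensure_min_prevalence > 0:
            geno = _enforce_prevalence(geno, f, config, rng)
        genos[locus.name] = geno
    return TruthSet(
        sites=list(config.sites),
        pop_sizes=list(config.pop_sizes),
        loci=list(config.loci),
        alleles=alleles,
        pop_allele_freqs=freqs,
        genotypes=genos,
        theta_fst=config.theta_fst,
    )


def expected_fst(freq_matrices: list[np.ndarray]) -> float:
    """Differentiation implied by known population allele frequencies.

    The infinite-sample limit of the Weir-Cockerham variance-component
    estimator with equal population weights: per allele, the among-population
    variance s2 over (pbar qbar + s2 / r), components summed over alleles and
    loci before the ratio.
    """
    num = den = 0.0
    for f in freq_matrices:
        f = np.asarray(f, dtype=float)
        r = f.shape[0]
        pbar = f.mean(axis=0)
        s2 = ((f - pbar) ** 2).sum(axis=0) / (r - 1)
        num += s2.sum()
        den += (pbar * (1.0 - pbar) + s2 / r).sum()
    return num / den


def expected_fprime_st(freq_matrices: list[np.ndarray]) -> float:
    """Standardized differentiation from known frequencies: expected FST
    divided by the FST of the recoding that makes every allele
    population-specific (maximal differentiation at the same
    within-population diversity)."""
    rec = []
    for f in freq_matrices:
        f = np.asarray(f, dtype=float)
        r, k = f.shape
        big = np.zeros((r, r * k))
        for i in range(r):
            big[i, i * k : (i + 1) * k] = f[i]
        rec.append(big)
    return expected_fst(freq_matrices) / expected_fst(rec)


def truth_genotype_matrix(truth: TruthSet, islands: dict[str, str] | None = None) -> "GenotypeMatrix":
    """The true genotypes as a GenotypeMatrix (no reads, no noise)."""
    from .genotypes import GenotypeMatrix

    colonies = truth.colony_ids
    n, L = len(colonies), len(truth.loci)
    alleles = np.empty((n, L, 2), dtype=np.int64)
    labels: dict[str, list] = {}
    for l, locus in enumerate(truth.loci):
        alleles[:, l, :] = truth.genotypes[locus.name]
        labels[locus.name] = [
            f"{a.repeats}.{a.variant}" for a in truth.alleles[locus.name]
        ]
    return GenotypeMatrix(
        individuals=[f"{s}_c{j:02d}" for s, j in colonies],
        populations=[s for s, _ in colonies],
        loci=[l.name for l in truth.loci],
        alleles=alleles,
        allele_labels=labels,
        encoding="unique_id",
        islands=dict(islands or {}),
    )


def _apply_point_errors(seqs: list[str], error_rate: float, rng: np.random.Generator) -> list[str]:
    if error_rate <= 0 or not seqs:
        return seqs
    lengths = np.array([len(s) for s in seqs])
    n_err = rng.binomial(lengths, error_rate)
    out = list(seqs)
    for i in np.nonzero(n_err)[0]:
        s = list(out[i])
        pos = rng.choice(lengths[i], size=n_err[i], replace=False)
        for p in pos:
            s[p] = BASES[(BASES.index(s[p]) + int(rng.integers(1, 4))) % 4]
        out[i] = "".join(s)
    return out


def simulate_read_set(
    truth: TruthSet,
    config: SimConfig,
    scheme: BarcodeScheme | None = None,
    out_dir: str | Path | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, list[tuple[str, str, str]]]:
    """Emit merged amplicon reads per site, with truth-preserving noise.

    Per colony-locus the total depth is negative binomial; reads split
    between the two alleles by a symmetric Beta draw; each read stutters
    (+-1 motif copy, floor at one repeat) with probability ``stutter_rate``
    and then accumulates per-base substitutions at ``error_rate``.  Reads are
    ``siteTag + colonyTag + fwd_primer + insert + rvs_primer`` with uniform
    high quality except a corrupted low-quality tail on a random fraction.

    Returns ``{site: [(read_id, sequence, quality), ...]}``; when ``out_dir``
    is given, one FASTQ per site is also written.
    """
    scheme = default_barcode_scheme(truth.sites) if scheme is None else scheme
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    for site in truth.sites:
        if site not in scheme.site_tags:
            raise ValueError(f"no site tag for {site}")
    for n in truth.pop_sizes:
        if n > scheme.n_colonies:
            raise ValueError("population larger than colony-tag capacity")

    k = config.depth_dispersion
    m = config.mean_depth
    nb_p = k / (k + m)
    reads: dict[str, list[tuple[str, str, str]]] = {s: [] for s in truth.sites}
    colonies = truth.colony_ids

    for locus in truth.loci:
        alleles = truth.alleles[locus.name]
        geno = truth.genotypes[locus.name]
        # cache of allele sequence by (repeats, variant), incl. stutter products
        seq_cache: dict[tuple[int, int], str] = {}

        def allele_seq(repeats: int, variant: int) -> str:
            key = (repeats, variant)
            if key not in seq_cache:
                lo, hi = locus.repeat_range
                r = max(1, repeats)
                left = _variant_flank(locus, variant)
                seq_cache[key] = left + locus.motif * r + locus.right_flank
            return seq_cache[key]

        depths = rng.negative_binomial(k, nb_p, size=len(colonies))
        balances = rng.beta(config.allele_balance_beta, config.allele_balance_beta, size=len(colonies))
        for idx, (site, j) in enumerate(colonies):
            depth = int(depths[idx])
            if depth == 0:
                continue
            a1, a2 = alleles[geno[idx, 0]], alleles[geno[idx, 1]]
            if a1 == a2:
                n1 = depth
            else:
                n1 = int(round(depth * balances[idx]))
            repeat_counts = np.array([a1.repeats] * n1 + [a2.repeats] * (depth - n1))
            variants = np.array([a1.variant] * n1 + [a2.variant] * (depth - n1))
            if config.stutter_rate > 0:
                stut = rng.random(depth) < config.stutter_rate
                step = rng.choice([-1, 1], size=depth)
                repeat_counts = np.where(stut, np.maximum(1, repeat_counts + step), repeat_counts)
            prefix = scheme.site_tags[site] + scheme.colony_tags[j] + locus.fwd_primer
            seqs = [
                prefix + allele_seq(int(r), int(v)) + locus.rvs_primer
                for r, v in zip(repeat_counts, variants)
            ]
            seqs = _apply_point_errors(seqs, config.error_rate, rng)
            tails = rng.random(depth) < config.lowq_tail_frac
            for ridx, s in enumerate(seqs):
                qual = "I" * len(s)
                if tails[ridx]:
                    t = int(rng.integers(5, 20))
                    t = min(t, len(s) - 1)
                    head, tail = s[:-t], list(s[-t:])
                    for p in range(t):  # corrupt the low-quality tail
                        if rng.random() < 0.2:
                            tail[p] = BASES[int(rng.integers(0, 4))]
                    s = head + "".join(tail)
                    qual = "I" * (len(s) - t) + "#" * t
                rid = f"{site}:c{j:02d}:{locus.name}:{ridx}"
                reads[site].append((rid, s, qual))
    for site in reads:
        order = rng.permutation(len(reads[site]))
        reads[site] = [reads[site][i] for i in order]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for site, recs in reads.items():
            write_fastq(out_dir / f"{site}.fastq", recs)
        truth.to_frame().to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return reads


def write_fastq(path: str | Path, records: list[tuple[str, str, str]]) -> None:
    """Write 4-line FASTQ; gzip if the path ends in .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
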