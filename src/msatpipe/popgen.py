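"""Diversity indices, AMOVA F-statistics, standardized differentiation,
exact tests and rarefied allelic richness on a GenotypeMatrix.

Estimators
----------
Diversity follows the Nei & Chesser small-sample corrections with the
harmonic-mean sample size n~ across populations::

    HS = (n~ / (n~ - 1)) * (1 - mean_pops sum_k p_k^2 - HO / (2 n~))
    HT = 1 - sum_k pbar_k^2 + HS / (n~ * npop)

from which GST = (HT - HS)/HT, Hedrick's G'ST, the corrected total
heterozygosity H'T, and Jost's D are derived.  F-statistics use the Weir &
Cockerham (1984) multiallelic variance components a (among populations),
b (among individuals within populations) and c (within individuals), summed
over alleles and loci; FST = sum a / sum(a+b+c), FIS = sum b / sum(b+c).
The standardized F'ST divides the observed FST by the FST of a recoded
matrix whose allele labels are made population-specific (maximum possible
differentiation given the within-population genotype structure).
Significance comes from permutation: individuals among populations for FST,
allele copies among individuals within populations for FIS.

Missing genotypes are handled by pairwise deletion throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "DiversityResult",
    "FstResult",
    "PairwiseMatrix",
    "apply_missing_filters",
    "diversity_indices",
    "amova_fstats",
    "standardized_fst",
    "pairwise_differentiation",
    "exact_test",
    "allelic_richness",
    "rarefied_richness",
]


# ---------------------------------------------------------------------------
# missing-data filters
# ---------------------------------------------------------------------------

def apply_missing_filters(
    matrix: GenotypeMatrix,
    max_locus_missing: float = 0.15,
    max_individual_missing: float = 0.35,
) -> GenotypeMatrix:
    """Keep loci with < ``max_locus_missing`` missing data, then individuals
    with < ``max_individual_missing`` missing over the retained loci."""
    miss = matrix.missing_mask
    locus_frac = miss.mean(axis=0)
    keep_loci = np.nonzero(locus_frac < max_locus_missing)[0]
    if keep_loci.size == 0:
        raise ValueError("all loci exceed the missing-data threshold")
    out = matrix.subset_loci(keep_loci)
    ind_frac = out.missing_mask.mean(axis=1)
    keep_ind = np.nonzero(ind_frac < max_individual_missing)[0]
    return out.subset_individuals(keep_ind)


# ---------------------------------------------------------------------------
# diversity indices (Nei-Chesser / Hedrick / Jost)
# ---------------------------------------------------------------------------

@dataclass
class DiversityResult:
    per_locus: pd.DataFrame
    overall: pd.Series
    monomorphic: list[str] = field(default_factory=list)


def _locus_diversity(matrix: GenotypeMatrix, l: int) -> dict | None:
    counts = matrix.allele_counts(l)  # (r, k) allele copies
    n_i = counts.sum(axis=1) / 2.0  # individuals genotyped per pop
    present = n_i > 0
    counts, n_i = counts[present], n_i[present]
    r = counts.shape[0]
    if r < 2 or n_i.min() < 2:
        return None
    p = counts / counts.sum(axis=1, keepdims=True)
    # observed heterozygosity per pop
    calls = matrix.alleles[:, l, :]
    ok = calls[:, 0] != MISSING
    het = ok & (calls[:, 0] != calls[:, 1])
    pops = matrix.pop_indices
    pop_ids = np.nonzero(present)[0]
    ho_pop = np.array(
        [het[pops == pid].sum() / max(ok[pops == pid].sum(), 1) for pid in pop_ids]
    )
    ho = ho_pop.mean()
    n_harm = r / (1.0 / n_i).sum()
    hs_plug = 1.0 - (p**2).sum(axis=1).mean()
    hs = (n_harm / (n_harm - 1.0)) * (hs_plug - ho / (2.0 * n_harm))
    pbar = p.mean(axis=0)
    ht = 1.0 - (pbar**2).sum() + hs / (n_harm * r)
    ne = 1.0 / (pbar**2).sum()
    n_alleles_total = int((counts.sum(axis=0) > 0).sum())
    out = {
        "n_pops": r,
        "n_alleles": n_alleles_total,
        "NE": ne,
        "HO": ho,
        "HS": hs,
        "HT": ht,
    }
    if n_alleles_total < 2 or ht <= 0:
        out.update(
            {"monomorphic": True, "HT_corrected": ht, "GST": np.nan, "G_ST_hedrick": np.nan, "D_jost": np.nan}
        )
        return out
    gst = (ht - hs) / ht
    gprime = gst * (r - 1.0 + hs) / ((r - 1.0) * (1.0 - hs)) if hs < 1 else np.nan
    htc = hs + (ht - hs) * r / (r - 1.0)
    d = (r / (r - 1.0)) * (ht - hs) / (1.0 - hs) if hs < 1 else np.nan
    out.update({"monomorphic": False, "HT_corrected": htc, "GST": gst, "G_ST_hedrick": gprime, "D_jost": d})
    return out


def diversity_indices(matrix: GenotypeMatrix) -> DiversityResult:
    """Per-locus and multilocus diversity and differentiation indices.

    Multilocus HO/HS/HT/H'T are unweighted locus averages; the multilocus
    ratio statistics (GST, G'ST, Jost's D) are computed from the averaged
    HS and HT, with monomorphic loci excluded and flagged.
    """
    if len(matrix.pop_names) < 2:
        raise ValueError("diversity_indices requires at least two populations")
    rows, mono = {}, []
    for l, locus in enumerate(matrix.loci):
        d = _locus_diversity(matrix, l)
        if d is None:
            continue
        if d.pop("monomorphic"):
            mono.append(locus)
        rows[locus] = d
    per_locus = pd.DataFrame.from_dict(rows, orient="index")
    poly = per_locus[~per_locus.index.isin(mono)]
    r = poly["n_pops"].iloc[0] if len(poly) else np.nan
    hs, ht = poly["HS"].mean(), poly["HT"].mean()
    ho = per_locus["HO"].mean()
    gst = (ht - hs) / ht
    overall = pd.Series(
        {
            "n_loci": len(per_locus),
            "N_alleles_mean": per_locus["n_alleles"].mean(),
            "NE": per_locus["NE"].mean(),
            "HO": ho,
            "HS": hs,
            "HT": ht,
            "HT_corrected": hs + (ht - hs) * r / (r - 1.0),
            "GST": gst,
            "G_ST_hedrick": gst * (r - 1.0 + hs) / ((r - 1.0) * (1.0 - hs)),
            "D_jost": (r / (r - 1.0)) * (ht - hs) / (1.0 - hs),
        }
    )
    return DiversityResult(per_locus=per_locus, overall=overall, monomorphic=mono)


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components and AMOVA-style F-statistics
# ---------------------------------------------------------------------------

def _wc_locus_components(
    calls: np.ndarray, pops: np.ndarray, n_pops: int, k: int
) -> tuple[float, float, float] | None:
    """Summed per-allele components (a, b, c) for one locus."""
    ok = calls[:, 0] != MISSING
    if ok.sum() == 0:
        return None
    calls = calls[ok]
    pops = pops[ok]
    counts = np.zeros((n_pops, k), dtype=float)
    np.add.at(counts, (pops, calls[:, 0]), 1)
    np.add.at(counts, (pops, calls[:, 1]), 1)
    n_i = counts.sum(axis=1) / 2.0
    present = n_i > 0
    counts, n_i = counts[present], n_i[present]
    r = counts.shape[0]
    if r < 2:
        return None
    het = calls[:, 0] != calls[:, 1]
    hcounts = np.zeros((n_pops, k), dtype=float)
    np.add.at(hcounts, (pops[het], calls[het, 0]), 1)
    np.add.at(hcounts, (pops[het], calls[het, 1]), 1)
    hcounts = hcounts[present]

    nbar = n_i.mean()
    if nbar <= 1:
        return None
    n_c = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1.0)
    if n_c <= 0:
        return None
    p = counts / (2.0 * n_i[:, None])
    h = hcounts / n_i[:, None]
    pbar = (n_i[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n_i[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
    hbar = (n_i[:, None] * h).sum(axis=0) / (r * nbar)
    pq = pbar * (1.0 - pbar)
    inner = pq - ((r - 1.0) / r) * s2 - hbar / 4.0
    a = (nbar / n_c) * (s2 - inner / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pq - ((r - 1.0) / r) * s2 - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
    c = hbar / 2.0
    return float(a.sum()), float(b.sum()), float(c.sum())


def _wc_fstats(alleles: np.ndarray, pops: np.ndarray, n_pops: int, ks: list[int]) -> tuple[float, float]:
    A = B = C = 0.0
    for l in range(alleles.shape[1]):
        comp = _wc_locus_components(alleles[:, l, :], pops, n_pops, ks[l])
        if comp is None:
            continue
        A += comp[0]
        B += comp[1]
        C += comp[2]
    denom = A + B + C
    fst = A / denom if denom > 0 else np.nan
    fis = B / (B + C) if (B + C) > 0 else np.nan
    return fst, fis


@dataclass
class FstResult:
    fst: float
    fis: float
    fst_max: float | None = None
    fprime_st: float | None = None
    p_fst: float | None = None
    p_fis: float | None = None
    n_permutations: int = 0


def _check_pops(matrix: GenotypeMatrix) -> None:
    pops = matrix.pop_indices
    for i, name in enumerate(matrix.pop_names):
        if (pops == i).sum() < 2:
            raise ValueError(f"population {name!r} has fewer than 2 individuals")


def amova_fstats(
    matrix: GenotypeMatrix,
    permutations: int = 20000,
    rng: np.random.Generator | None = None,
) -> FstResult:
    """Weir-Cockerham FST and FIS with permutation p-values.

    FST significance permutes individuals among populations; FIS permutes
    allele copies among individuals within each population.  p-values use
    the add-one rule (#{perm >= obs} + 1)/(n + 1).
    """
    if len(matrix.pop_names) < 2:
        raise ValueError("amova_fstats requires at least two populations")
    _check_pops(matrix)
    rng = np.random.default_rng(0) if rng is None else rng
    pops = matrix.pop_indices
    r = len(matrix.pop_names)
    ks = [matrix.n_alleles(l) for l in matrix.loci]
    fst, fis = _wc_fstats(matrix.alleles, pops, r, ks)
    p_fst = p_fis = None
    if permutations > 0:
        hits = 0
        for _ in range(permutations):
            perm = rng.permutation(pops)
            f, _ = _wc_fstats(matrix.alleles, perm, r, ks)
            if not np.isnan(f) and f >= fst:
                hits += 1
        p_fst = (hits + 1) / (permutations + 1)
        hits = 0
        base = matrix.alleles
        for _ in range(permutations):
            shuffled = base.copy()
            for l in range(base.shape[1]):
                calls = shuffled[:, l, :]
                for pid in range(r):
                    sel = (pops == pid) & (calls[:, 0] != MISSING)
                    copies = calls[sel].ravel()
                    rng.shuffle(copies)
                    calls[sel] = copies.reshape(-1, 2)
            _, f = _wc_fstats(shuffled, pops, r, ks)
            if not np.isnan(f) and f >= fis:
                hits += 1
        p_fis = (hits + 1) / (permutations + 1)
    return FstResult(fst=fst, fis=fis, p_fst=p_fst, p_fis=p_fis, n_permutations=permutations)


def _recode_max(matrix: GenotypeMatrix) -> tuple[np.ndarray, list[int]]:
    """Population-specific allele labels: same genotype structure, zero
    allele sharing between populations (the maximal-differentiation recode)."""
    pops = matrix.pop_indices
    r = len(matrix.pop_names)
    alleles = matrix.alleles.copy()
    ks = []
    for l, locus in enumerate(matrix.loci):
        k = matrix.n_alleles(locus)
        calls = alleles[:, l, :]
        ok = calls[:, 0] != MISSING
        calls[ok] = pops[ok, None] * k + calls[ok]
        ks.append(r * k)
    return alleles, ks


def standardized_fst(
    matrix: GenotypeMatrix,
    permutations: int = 20000,
    rng: np.random.Generator | None = None,
) -> FstResult:
    """Meirmans-standardized F'ST = FST / FST(max).

    FST(max) is the Weir-Cockerham FST of the recoded matrix in which every
    allele label is made population-specific.  The p-value is inherited from
    the FST permutation test.
    """
    res = amova_fstats(matrix, permutations=permutations, rng=rng)
    if not np.isfinite(res.fst):
        raise ValueError("FST undefined: no polymorphism in any locus")
    rec_alleles, ks = _recode_max(matrix)
    fst_max, _ = _wc_fstats(rec_alleles, matrix.pop_indices, len(matrix.pop_names), ks)
    if not np.isfinite(fst_max) or fst_max <= 0:
        raise ValueError("FST(max) is zero: populations monomorphic and identical")
    res.fst_max = fst_max
    res.fprime_st = res.fst / fst_max
    return res


@dataclass
class PairwiseMatrix:
    """Statistic above the diagonal, permutation p-values below."""

    labels: list[str]
    values: pd.DataFrame
    n_permutations: int

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values.iloc[min(i, j), max(i, j)])

    def p_value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values.iloc[max(i, j), min(i, j)])


def pairwise_differentiation(
    matrix: GenotypeMatrix,
    level: str = "site",
    permutations: int = 20000,
    rng: np.random.Generator | None = None,
) -> PairwiseMatrix:
    """Pairwise standardized F'ST between sites or islands."""
    rng = np.random.default_rng(0) if rng is None else rng
    work = matrix.grouped_by_island() if level == "island" else matrix
    groups = work.pop_names
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    table = pd.DataFrame(np.nan, index=groups, columns=groups)
    for i, ga in enumerate(groups):
        for j in range(i + 1, len(groups)):
            gb = groups[j]
            sub = work.subset_pops([ga, gb])
            sizes = pd.Series(sub.populations).value_counts()
            if sizes.min() < 2 or len(sizes) < 2:
                continue
            res = standardized_fst(sub, permutations=permutations, rng=rng)
            table.iloc[i, j] = res.fprime_st
            table.iloc[j, i] = res.p_fst
    return PairwiseMatrix(labels=groups, values=table, n_permutations=permutations)


# ---------------------------------------------------------------------------
# exact tests of population differentiation
# ---------------------------------------------------------------------------

def _table_logprob(x1: np.ndarray, colors: np.ndarray, n1: int) -> np.ndarray:
    """Log conditional probability of 2 x k tables given margins."""
    N = colors.sum()
    x1 = np.atleast_2d(x1)
    lp = gammaln(colors + 1) - gammaln(x1 + 1) - gammaln(colors - x1 + 1)
    return lp.sum(axis=1) - (gammaln(N + 1) - gammaln(n1 + 1) - gammaln(N - n1 + 1))


def exact_test(
    matrix: GenotypeMatrix,
    steps: int = 100_000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Monte-Carlo exact probability test of differentiation per pop pair.

    Per locus the observed populations x alleles allele-count table is
    compared with ``steps`` tables sampled from the conditional null
    (multivariate hypergeometric, margins held fixed); the p-value is the
    add-one-corrected fraction of sampled tables whose conditional
    probability is at most the observed table's.  Loci are combined per pair
    with Fisher's method (chi-square with 2L degrees of freedom).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    pops = matrix.pop_names
    rows = []
    for i, ga in enumerate(pops):
        for gb in pops[i + 1 :]:
            sub = matrix.subset_pops([ga, gb])
            pidx = sub.pop_indices
            locus_ps = {}
            for l, locus in enumerate(sub.loci):
                counts = sub.allele_counts(l)
                if counts.shape[0] < 2:
                    continue
                seen = counts.sum(axis=0) > 0
                if seen.sum() < 2:
                    continue  # monomorphic in both populations
                counts = counts[:, seen]
                colors = counts.sum(axis=0).astype(np.int64)
                n1 = int(counts[0].sum())
                obs_lp = _table_logprob(counts[0], colors, n1)[0]
                sims = rng.multivariate_hypergeometric(colors, n1, size=steps)
                sim_lp = _table_logprob(sims, colors, n1)
                p = ((sim_lp <= obs_lp + 1e-9).sum() + 1) / (steps + 1)
                locus_ps[locus] = p
                rows.append({"pop1": ga, "pop2": gb, "locus": locus, "p": p})
            if locus_ps:
                ps = np.array(list(locus_ps.values()))
                x2 = -2.0 * np.log(ps).sum()
                combined = float(stats.chi2.sf(x2, 2 * len(ps)))
                rows.append({"pop1": ga, "pop2": gb, "locus": "combined", "p": combined})
    return pd.DataFrame(rows, columns=["pop1", "pop2", "locus", "p"])


# ---------------------------------------------------------------------------
# rarefied allelic richness
# ---------------------------------------------------------------------------

def rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected number of alleles in a subsample of g gene copies.

    AR = sum_i [1 - C(N - N_i, g) / C(N, g)] with N the total copies and
    N_i the copies of allele i.  Requires N >= g.
    """
    counts = np.asarray([c for c in counts if c > 0], dtype=np.int64)
    N = counts.sum()
    if g < 1:
        raise ValueError("g must be >= 1")
    if N < g:
        raise ValueError("sample smaller than rarefaction size")

    def log_comb(n: np.ndarray | int, k: int) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = N - counts
    frac = np.where(rest >= g, np.exp(log_comb(rest, g) - log_comb(N, g)), 0.0)
    return float((1.0 - frac).sum())


def allelic_richness(matrix: GenotypeMatrix, rarefaction_colonies: int = 24) -> pd.DataFrame:
    """Per-locus, per-population rarefied allelic richness (plus a pooled
    "Total" column), standardized to ``2 * rarefaction_colonies`` gene
    copies.  Populations with too few genotyped colonies at a locus are
    flagged with NaN rather than extrapolated."""
    g = 2 * rarefaction_colonies
    cols = matrix.pop_names + ["Total"]
    out = pd.DataFrame(index=matrix.loci, columns=cols, dtype=float)
    for l, locus in enumerate(matrix.loci):
        counts = matrix.allele_counts(l)
        for pi, pop in enumerate(matrix.pop_names):
            c = counts[pi]
            if c.sum() >= g:
                out.loc[locus, pop] = rarefied_richness(c, g)
        total = counts.sum(axis=0)
        if total.sum() >= g:
            out.loc[locus, "Total"] = rarefied_richness(total, g)
    return out
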