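"""Heterozygosity-excess and mode-shift tests for recent bottlenecks.

After a bottleneck, rare alleles are lost faster than heterozygosity, so the
observed expected heterozygosity He transiently exceeds the equilibrium
value Heq expected for the observed allele count.  Per locus, Heq is the
distribution of sample heterozygosity in coalescent simulations of the same
number of gene copies, with the mutation parameter theta calibrated so the
mean simulated allele count matches the observed count, retaining only
simulations with exactly that count.  A one-tailed Wilcoxon signed-rank test
across loci then asks whether He - mean(Heq) is systematically positive.

Two mutation models are provided: the infinite-allele model (IAM, every
mutation is novel; simulated by the Hoppe-urn representation of the
coalescent, which is exact and fast) and a two-phase model (TPM, a fraction
``p_stepwise`` of mutations step one repeat unit, the rest make geometric
multi-repeat jumps; simulated on explicit Kingman genealogies).

The graphical mode-shift test bins all allele frequencies of a population
into ten classes of width 0.1; at mutation-drift equilibrium the
lowest-frequency class dominates (an L shape), and a mode shifted away from
it is the bottleneck signature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

__all__ = [
    "MutationModel",
    "BottleneckResult",
    "simulate_heq",
    "het_excess_test",
    "mode_shift_test",
    "equilibrium_population",
    "founder_reduction",
    "ewens_expected_alleles",
]


@dataclass(frozen=True)
class MutationModel:
    """IAM or TPM; ``multistep_var`` sets the geometric jump-size variance."""

    kind: str = "TPM"
    p_stepwise: float = 0.70
    multistep_var: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in ("IAM", "TPM"):
            raise ValueError("kind must be IAM or TPM")
        if not 0 <= self.p_stepwise <= 1:
            raise ValueError("p_stepwise must be in [0, 1]")

    @property
    def geom_p(self) -> float:
        """Success parameter of the geometric jump size on {1, 2, ...} whose
        variance equals ``multistep_var``."""
        v = self.multistep_var
        return (math.sqrt(1.0 + 4.0 * v) - 1.0) / (2.0 * v)


IAM = MutationModel("IAM")
TPM = MutationModel("TPM")


def ewens_expected_alleles(theta: float, n: int) -> float:
    """Expected number of alleles in a sample of n genes under the IAM:
    sum_{i=0}^{n-1} theta / (theta + i)."""
    i = np.arange(n)
    return float((theta / (theta + i)).sum())


# ---------------------------------------------------------------------------
# IAM: Hoppe-urn samples of the coalescent with infinite alleles
# ---------------------------------------------------------------------------

def _iam_batch(n: int, theta: float, n_sims: int, rng: np.random.Generator) -> np.ndarray:
    """Allele labels (n_sims, n) drawn from the Ewens sampling distribution."""
    labels = np.zeros((n_sims, n), dtype=np.int64)
    next_label = np.ones(n_sims, dtype=np.int64)
    rows = np.arange(n_sims)
    for i in range(1, n):
        novel = rng.random(n_sims) < theta / (theta + i)
        j = rng.integers(0, i, size=n_sims)
        labels[:, i] = np.where(novel, next_label, labels[rows, j])
        next_label += novel
    return labels


def _summaries(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(allele count, sum of squared copy counts) per row."""
    n_sims, n = labels.shape
    flat = (labels + (np.arange(n_sims) * n)[:, None]).ravel()
    counts = np.bincount(flat, minlength=n_sims * n).reshape(n_sims, n)
    k = (counts > 0).sum(axis=1)
    sumsq = (counts.astype(np.float64) ** 2).sum(axis=1)
    return k, sumsq


# ---------------------------------------------------------------------------
# TPM: explicit Kingman genealogies with two-phase repeat mutations
# ---------------------------------------------------------------------------

def _kingman_tree(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random coalescent genealogy: parent pointers and node times.

    Leaves are nodes 0..n-1 at time 0; internal nodes are created in time
    order, so every parent has a higher index than its children.  Time is in
    units of 2N generations.
    """
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=np.int64)
    time = np.zeros(total)
    active = np.arange(n)
    k_range = np.arange(n, 1, -1)
    waits = rng.exponential(2.0 / (k_range * (k_range - 1)))
    times = np.cumsum(waits)
    u1 = rng.integers(0, k_range)
    u2 = rng.integers(0, k_range - 1)
    for merge in range(n - 1):
        k = n - merge
        i = u1[merge]
        j = u2[merge]
        if j >= i:
            j += 1
        nxt = n + merge
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = times[merge]
        # replace slot i with the new node, swap slot j with the last slot
        active[i] = nxt
        active[j] = active[k - 1]
    return parent, time


def _tpm_once(
    n: int, theta: float, model: MutationModel, rng: np.random.Generator
) -> np.ndarray:
    """Leaf repeat-count states for one TPM coalescent simulation."""
    parent, time = _kingman_tree(n, rng)
    total = parent.size
    branch = np.zeros(total)
    has_parent = parent >= 0
    branch[has_parent] = time[parent[has_parent]] - time[has_parent]
    nmut = rng.poisson(branch * theta / 2.0)
    step = np.zeros(total)
    M = int(nmut.sum())
    if M:
        signs = 1.0 - 2.0 * rng.integers(0, 2, size=M)
        one_step = rng.random(M) < model.p_stepwise
        sizes = np.where(one_step, 1, rng.geometric(model.geom_p, size=M))
        idx = np.repeat(np.arange(total), nmut)
        np.add.at(step, idx, signs * sizes)
    state = np.zeros(total)
    # parents always have higher indices: propagate root -> leaves
    for node in range(total - 2, -1, -1):
        state[node] = state[parent[node]] + step[node]
    return state[:n]


def _tpm_mean_k(n: int, theta: float, model: MutationModel, sims: int, rng) -> float:
    ks = [np.unique(_tpm_once(n, theta, model, rng)).size for _ in range(sims)]
    return float(np.mean(ks))


# ---------------------------------------------------------------------------
# Heq simulation with theta calibration
# ---------------------------------------------------------------------------

def _calibrate_theta_iam(n: int, k_obs: int) -> float:
    if k_obs >= n:
        return 1e7
    lo, hi = 1e-6, 1e7
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if ewens_expected_alleles(mid, n) < k_obs:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.0 + 1e-10:
            break
    return math.sqrt(lo * hi)


def _calibrate_theta_tpm(
    n: int, k_obs: int, model: MutationModel, rng: np.random.Generator, sims: int = 200
) -> float:
    lo, hi = 1e-3, 1e5
    for _ in range(14):
        mid = math.sqrt(lo * hi)
        if _tpm_mean_k(n, mid, model, sims, rng) < k_obs:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def simulate_heq(
    n_genes: int,
    k_obs: int,
    model: MutationModel,
    n_iter: int = 10000,
    rng: np.random.Generator | None = None,
    max_batches: int = 40,
) -> np.ndarray:
    """Equilibrium heterozygosity distribution conditional on ``k_obs``.

    theta is calibrated (closed form via the Ewens expectation for the IAM,
    Monte-Carlo bisection for the TPM) so the mean simulated allele count
    equals ``k_obs``; simulations are retained only when they produce exactly
    ``k_obs`` alleles, and heterozygosity uses the same small-sample
    correction as the observed values: Heq = (n/(n-1)) (1 - sum p_hat^2).
    """
    if not 2 <= k_obs <= n_genes:
        raise ValueError("need 2 <= k_obs <= n_genes")
    rng = np.random.default_rng(0) if rng is None else rng
    n = n_genes
    out: list[np.ndarray] = []
    attempts = 0
    if model.kind == "IAM":
        theta = _calibrate_theta_iam(n, k_obs)
        batch = max(n_iter, 2000)
        for _ in range(max_batches):
            labels = _iam_batch(n, theta, batch, rng)
            k, sumsq = _summaries(labels)
            keep = k == k_obs
            het = (1.0 - sumsq[keep] / n**2) * n / (n - 1.0)
            out.append(het)
            attempts += batch
            if sum(len(o) for o in out) >= n_iter:
                break
    else:
        theta = _calibrate_theta_tpm(n, k_obs, model, rng)
        vals: list[float] = []
        max_attempts = max_batches * max(n_iter, 2000)
        while len(vals) < n_iter and attempts < max_attempts:
            states = _tpm_once(n, theta, model, rng)
            attempts += 1
            _, counts = np.unique(states, return_counts=True)
            if counts.size == k_obs:
                vals.append((1.0 - (counts.astype(float) ** 2).sum() / n**2) * n / (n - 1.0))
        out.append(np.array(vals))
    heq = np.concatenate(out)[:n_iter]
    if heq.size < max(30, n_iter // 100):
        raise RuntimeError(
            f"Heq calibration failed: n={n_genes}, k={k_obs}, model={model.kind}, "
            f"theta={theta:.4g}, retained {heq.size} of {attempts} simulations"
        )
    return heq


# ---------------------------------------------------------------------------
# tests on genotype matrices
# ---------------------------------------------------------------------------

@dataclass
class BottleneckResult:
    population: str
    model: MutationModel
    per_locus: pd.DataFrame
    wilcoxon_p: float
    n_iter: int


def _pop_allele_counts(matrix: GenotypeMatrix, population: str) -> dict[str, np.ndarray]:
    sub = matrix.subset_pops([population])
    out = {}
    for l, locus in enumerate(sub.loci):
        counts = sub.allele_counts(l, by_pop=False)
        out[locus] = counts[counts > 0]
    return out


def het_excess_test(
    matrix: GenotypeMatrix,
    population: str,
    model: MutationModel = TPM,
    n_iter: int = 10000,
    rng: np.random.Generator | None = None,
) -> BottleneckResult:
    """One-tailed Wilcoxon signed-rank test for heterozygosity excess.

    Per polymorphic locus: the unbiased expected heterozygosity He (Nei,
    n/(n-1)-corrected), the simulated Heq mean and sd, the standardized
    difference DH = (He - mean Heq)/sd(Heq), and P(He >= Heq).  The Wilcoxon
    test is across loci on He - mean(Heq), alternative "greater".
    """
    rng = np.random.default_rng(0) if rng is None else rng
    rows = []
    for locus, counts in _pop_allele_counts(matrix, population).items():
        n = int(counts.sum())
        k = counts.size
        if k < 2 or n < 4:
            continue
        he = (1.0 - ((counts / n) ** 2).sum()) * n / (n - 1.0)
        heq = simulate_heq(n, k, model, n_iter=n_iter, rng=rng)
        sd = heq.std(ddof=1)
        rows.append(
            {
                "locus": locus,
                "n_genes": n,
                "k_obs": k,
                "He_obs": he,
                "Heq_mean": heq.mean(),
                "Heq_sd": sd,
                "DH": (he - heq.mean()) / sd if sd > 0 else np.nan,
                "P_He_ge_sim": float((heq <= he).mean()),
            }
        )
    per_locus = pd.DataFrame(rows)
    if len(per_locus) < 4:
        warnings.warn(
            f"{population}: only {len(per_locus)} polymorphic loci; the Wilcoxon "
            "test has little power below 4",
            stacklevel=2,
        )
    diffs = (per_locus["He_obs"] - per_locus["Heq_mean"]).to_numpy()
    p = float(stats.wilcoxon(diffs, alternative="greater", method="exact").pvalue)
    return BottleneckResult(population, model, per_locus, p, n_iter)


def mode_shift_test(matrix: GenotypeMatrix, population: str) -> tuple[np.ndarray, str]:
    """Allele-frequency histogram over ten left-open classes and the verdict.

    "L-shaped" iff the (0, 0.1] class holds strictly more alleles than every
    other class; otherwise "mode-shifted".  Frequencies exactly on a bin
    edge fall in the lower bin.
    """
    counts = np.zeros(10, dtype=np.int64)
    any_poly = False
    for locus, allele_counts in _pop_allele_counts(matrix, population).items():
        n = allele_counts.sum()
        if allele_counts.size < 2:
            continue
        any_poly = True
        freqs = allele_counts / n
        bins = np.ceil(freqs * 10.0 - 1e-12).astype(int) - 1
        np.add.at(counts, np.clip(bins, 0, 9), 1)
    if not any_poly:
        raise ValueError(f"{population}: no polymorphic loci; mode-shift verdict undefined")
    verdict = "L-shaped" if counts[0] > counts[1:].max() else "mode-shifted"
    return counts, verdict


# ---------------------------------------------------------------------------
# equilibrium and founder-reduction populations (simulation harness)
# ---------------------------------------------------------------------------

def equilibrium_population(
    n_individuals: int,
    n_loci: int,
    theta: float,
    model: MutationModel = IAM,
    rng: np.random.Generator | None = None,
    name: str = "pop",
) -> GenotypeMatrix:
    """Sample a mutation-drift-equilibrium diploid population.

    Each locus is an independent coalescent sample of 2N gene copies (Hoppe
    urn for IAM, genealogy simulation for TPM) paired into diploids.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    n = 2 * n_individuals
    alleles = np.empty((n_individuals, n_loci, 2), dtype=np.int64)
    labels = {}
    for l in range(n_loci):
        if model.kind == "IAM":
            genes = _iam_batch(n, theta, 1, rng)[0]
        else:
            genes = _tpm_once(n, theta, model, rng)
        uniq, inv = np.unique(genes, return_inverse=True)
        inv = rng.permutation(inv)
        alleles[:, l, 0] = inv[:n_individuals]
        alleles[:, l, 1] = inv[n_individuals:]
        labels[f"L{l + 1}"] = [int(x) if float(x) == int(x) else float(x) for x in uniq]
    return GenotypeMatrix(
        individuals=[f"{name}_{i:03d}" for i in range(n_individuals)],
        populations=[name] * n_individuals,
        loci=[f"L{l + 1}" for l in range(n_loci)],
        alleles=alleles,
        allele_labels=labels,
    )


def founder_reduction(
    matrix: GenotypeMatrix,
    survival: float = 0.05,
    generations: int = 3,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Bottleneck a population and drift it forward without mutation.

    A random fraction ``survival`` of individuals founds the next
    generation; subsequent generations are Wright-Fisher draws at the
    reduced size.  The returned sample has the original number of
    individuals, drawn from the final generation's gene pool.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    n = matrix.n_individuals
    L = matrix.n_loci
    nb = max(2, int(round(survival * n)))
    keep = rng.choice(n, size=nb, replace=False)
    pool = matrix.alleles[keep]
    cols = np.arange(L)[None, :]

    def wf_offspring(pool: np.ndarray, n_off: int) -> np.ndarray:
        new = np.empty((n_off, L, 2), dtype=np.int64)
        for slot in (0, 1):  # one gamete from each of two random parents
            parents = rng.integers(0, pool.shape[0], size=n_off)
            which = rng.integers(0, 2, size=(n_off, L))
            new[:, :, slot] = pool[parents[:, None], cols, which]
        return new

    for _ in range(generations):
        pool = wf_offspring(pool, nb)
    out = wf_offspring(pool, n)
    return GenotypeMatrix(
        individuals=list(matrix.individuals),
        populations=list(matrix.populations),
        loci=list(matrix.loci),
        alleles=out,
        allele_labels=dict(matrix.allele_labels),
        islands=dict(matrix.islands),
    )
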