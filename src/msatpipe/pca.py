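"""Covariance-matrix PCA of individuals and of populations.

Individuals are represented by allele-indicator counts (0/1/2 copies of each
allele at each locus, missing genotypes mean-imputed per column);
populations by their allele-frequency vectors.  Axis significance is
assessed by permutation: each column is shuffled independently, destroying
between-object structure while keeping per-column distributions, and the
observed eigenvalues are compared rank-for-rank with the permuted ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = ["PCAResult", "pca_individuals", "pca_populations", "indicator_matrix"]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # objects x axes
    eigenvalues: np.ndarray
    explained: np.ndarray  # fraction of total variance per axis
    p_values: np.ndarray | None
    metadata: pd.DataFrame  # site / island per object

    @property
    def n_axes(self) -> int:
        return self.eigenvalues.size


def indicator_matrix(matrix: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    """Individuals x alleles count matrix (0/1/2), missing mean-imputed."""
    blocks, names = [], []
    for l, locus in enumerate(matrix.loci):
        k = matrix.n_alleles(locus)
        calls = matrix.alleles[:, l, :]
        ok = calls[:, 0] != MISSING
        block = np.zeros((matrix.n_individuals, k))
        rows = np.nonzero(ok)[0]
        for slot in (0, 1):
            np.add.at(block, (rows, calls[rows, slot]), 1.0)
        if ok.any() and (~ok).any():
            block[~ok] = block[ok].mean(axis=0)
        blocks.append(block)
        names.extend(f"{locus}:{lab}" for lab in matrix.allele_labels[locus])
    return np.concatenate(blocks, axis=1), names


def _pca_core(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-center, eigendecompose the covariance, fix sign convention
    (largest-magnitude loading positive per axis)."""
    Xc = X - X.mean(axis=0)
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    scores = U * s
    for a in range(Vt.shape[0]):
        lead = np.argmax(np.abs(Vt[a]))
        if Vt[a, lead] < 0:
            scores[:, a] *= -1.0
    keep = eig > max(eig.max(), 1.0) * 1e-12 if eig.size else np.array([], bool)
    return scores[:, keep], eig[keep], eig


def _permutation_p(
    X: np.ndarray, observed: np.ndarray, permutations: int, rng: np.random.Generator
) -> np.ndarray:
    n_axes = observed.size
    exceed = np.zeros(n_axes)
    Xp = X.copy()
    for _ in range(permutations):
        for c in range(Xp.shape[1]):
            rng.shuffle(Xp[:, c])
        _, eig, _ = _pca_core(Xp)
        m = min(eig.size, n_axes)
        exceed[:m] += eig[:m] >= observed[:m]
    return exceed / permutations


def _run_pca(
    X: np.ndarray,
    labels: list[str],
    meta: pd.DataFrame,
    permutations: int,
    rng: np.random.Generator | None,
) -> PCAResult:
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 objects")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("zero-variance matrix")
    rng = np.random.default_rng(0) if rng is None else rng
    scores, eig, all_eig = _pca_core(X)
    explained = eig / all_eig.sum()
    p = _permutation_p(X, eig, permutations, rng) if permutations > 0 else None
    frame = pd.DataFrame(
        scores, index=labels, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
    )
    return PCAResult(frame, eig, explained, p, meta)


def pca_individuals(
    matrix: GenotypeMatrix,
    permutations: int = 10000,
    rng: np.random.Generator | None = None,
) -> PCAResult:
    """PCA of individuals on the allele-indicator covariance matrix."""
    X, _ = indicator_matrix(matrix)
    meta = pd.DataFrame(
        {
            "site": matrix.populations,
            "island": [matrix.island_of(p) for p in matrix.populations],
        },
        index=matrix.individuals,
    )
    return _run_pca(X, matrix.individuals, meta, permutations, rng)


def pca_populations(
    matrix: GenotypeMatrix,
    permutations: int = 10000,
    rng: np.random.Generator | None = None,
) -> PCAResult:
    """PCA of populations on their allele-frequency vectors."""
    pops = matrix.pop_names
    if len(pops) < 3:
        raise ValueError("population PCA needs at least 3 populations")
    blocks = []
    for l in range(matrix.n_loci):
        counts = matrix.allele_counts(l).astype(float)
        totals = counts.sum(axis=1, keepdims=True)
        freqs = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
        blocks.append(freqs)
    X = np.concatenate(blocks, axis=1)
    meta = pd.DataFrame({"island": [matrix.island_of(p) for p in pops]}, index=pops)
    return _run_pca(X, pops, meta, permutations, rng)
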