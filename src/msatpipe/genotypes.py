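"""Diploid genotype matrix with population labels and explicit missing data."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "MISSING"]

#: Sentinel allele index for a missing call.
MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid allele calls.

    ``alleles[i, l, :]`` are indices into ``allele_labels[loci[l]]``; both
    slots are ``MISSING`` (-1) for a missing call - never an empty string.
    ``encoding`` records whether allele labels denote repeat-region lengths
    ("length") or unique sequence identities ("unique_id").
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    alleles: np.ndarray
    allele_labels: dict[str, list]
    encoding: str = "unique_id"
    islands: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, L = len(self.individuals), len(self.loci)
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.alleles.shape != (n, L, 2):
            raise ValueError(f"alleles must have shape ({n}, {L}, 2)")
        if len(self.populations) != n:
            raise ValueError("populations must match individuals")
        half_missing = (self.alleles == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("missing calls must blank both allele slots")

    # -- basic structure -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def pop_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    @property
    def pop_indices(self) -> np.ndarray:
        order = {p: i for i, p in enumerate(self.pop_names)}
        return np.array([order[p] for p in self.populations], dtype=np.int64)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (individuals, loci); True where the call is missing."""
        return self.alleles[:, :, 0] == MISSING

    def island_of(self, pop: str) -> str:
        return self.islands.get(pop, pop)

    # -- subsetting ------------------------------------------------------
    def subset_individuals(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            individuals=[self.individuals[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            alleles=self.alleles[idx],
        )

    def subset_loci(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        loci = [self.loci[i] for i in idx]
        return replace(
            self,
            loci=loci,
            alleles=self.alleles[:, idx],
            allele_labels={l: self.allele_labels[l] for l in loci},
        )

    def subset_pops(self, pops: list[str]) -> "GenotypeMatrix":
        keep = set(pops)
        idx = [i for i, p in enumerate(self.populations) if p in keep]
        return self.subset_individuals(idx)

    def grouped_by_island(self) -> "GenotypeMatrix":
        """Same data with island labels as populations."""
        return replace(self, populations=[self.island_of(p) for p in self.populations])

    # -- counting --------------------------------------------------------
    def n_alleles(self, locus: str) -> int:
        return len(self.allele_labels[locus])

    def allele_counts(self, locus_idx: int, by_pop: bool = True) -> np.ndarray:
        """Allele-copy counts; shape (n_pops, k) or (k,).  Missing calls are
        excluded (pairwise deletion)."""
        k = self.n_alleles(self.loci[locus_idx])
        calls = self.alleles[:, locus_idx, :]
        ok = calls[:, 0] != MISSING
        flat = calls[ok].ravel()
        if not by_pop:
            return np.bincount(flat, minlength=k)
        pops = np.repeat(self.pop_indices[ok], 2)
        r = len(self.pop_names)
        return np.bincount(pops * k + flat, minlength=r * k).reshape(r, k)

    # -- tables ----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format table: individual, population, locus, allele1, allele2."""
        rows = []
        for i, ind in enumerate(self.individuals):
            for l, locus in enumerate(self.loci):
                a1, a2 = self.alleles[i, l]
                labels = self.allele_labels[locus]
                rows.append(
                    {
                        "individual": ind,
                        "population": self.populations[i],
                        "locus": locus,
                        "allele1": labels[a1] if a1 != MISSING else None,
                        "allele2": labels[a2] if a2 != MISSING else None,
                    }
                )
        return pd.DataFrame(rows)

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Same individuals, loci and (unordered) allele labels per call."""
        if self.individuals != other.individuals or self.loci != other.loci:
            return False
        for l, locus in enumerate(self.loci):
            mine = self.allele_labels[locus]
            theirs = other.allele_labels[locus]
            for i in range(self.n_individuals):
                a = self.alleles[i, l]
                b = other.alleles[i, l]
                pa = sorted(str(mine[x]) for x in a if x != MISSING)
                pb = sorted(str(theirs[x]) for x in b if x != MISSING)
                if pa != pb:
                    return False
        return True
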