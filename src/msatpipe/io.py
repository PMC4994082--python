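"""Genotype file formats: genepop and the native long-format table."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .loci import LocusSpec

__all__ = ["genepop_write", "genepop_read", "write_genotype_table", "read_genotype_table"]


def _allele_codes(matrix: GenotypeMatrix, loci: list[LocusSpec] | None) -> dict[str, dict]:
    """Label -> 3-digit genepop code per locus.

    Length-encoded matrices use repeat-unit counts when locus metadata is
    available (label = repeat-region length divided by motif size),
    otherwise the length itself; unique-ID matrices use their integer labels.
    """
    motif_len = {l.name: len(l.motif) for l in loci} if loci else {}
    codes: dict[str, dict] = {}
    for locus in matrix.loci:
        table = {}
        for lab in matrix.allele_labels[locus]:
            if matrix.encoding == "length" and locus in motif_len:
                code = int(round(int(lab) / motif_len[locus]))
            else:
                code = int(lab)
            if not 1 <= code <= 999:
                raise ValueError(f"{locus}: allele code {code} outside 001-999")
            table[lab] = code
        if len(set(table.values())) != len(table):
            raise ValueError(f"{locus}: allele codes collide")
        codes[locus] = table
    return codes


def genepop_write(
    matrix: GenotypeMatrix,
    path: str | Path,
    title: str | None = None,
    loci: list[LocusSpec] | None = None,
) -> None:
    """Write a genepop file (3-digit diploid codes, 000000 = missing)."""
    codes = _allele_codes(matrix, loci)
    lines = [title or f"msatpipe genotypes ({matrix.encoding} encoding)"]
    lines.extend(matrix.loci)
    pops = matrix.pop_names
    pidx = matrix.pop_indices
    for p, pop in enumerate(pops):
        lines.append("Pop")
        for i in np.nonzero(pidx == p)[0]:
            parts = []
            for l, locus in enumerate(matrix.loci):
                a1, a2 = matrix.alleles[i, l]
                if a1 == MISSING:
                    parts.append("000000")
                else:
                    labels = matrix.allele_labels[locus]
                    parts.append(f"{codes[locus][labels[a1]]:03d}{codes[locus][labels[a2]]:03d}")
            lines.append(f"{matrix.individuals[i]} ,  " + " ".join(parts))
    Path(path).write_text("\n".join(lines) + "\n")


def genepop_read(path: str | Path, islands: dict[str, str] | None = None) -> GenotypeMatrix:
    """Parse a genepop file back into a GenotypeMatrix.

    Allele labels are the integer codes.  Population labels follow the
    convention used by the writer: the individual-id prefix before the first
    underscore, falling back to ``pop<N>``.
    """
    text = Path(path).read_text().splitlines()
    if len(text) < 3:
        raise ValueError(f"{path}: not a genepop file (fewer than 3 lines)")
    loci: list[str] = []
    i = 1
    while i < len(text) and text[i].strip().lower() != "pop":
        # locus names: one per line, or comma-separated on one line
        loci.extend(x.strip() for x in text[i].split(",") if x.strip())
        i += 1
    if i == len(text):
        raise ValueError(f"{path}: no 'Pop' line found")
    individuals: list[str] = []
    populations: list[str] = []
    raw: list[list[tuple[int, int]]] = []
    pop_counter = 0
    for lineno in range(i, len(text)):
        line = text[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_counter += 1
            continue
        if "," not in line:
            raise ValueError(f"{path}:{lineno + 1}: expected 'name , genotypes'")
        name, geno = line.split(",", 1)
        name = name.strip()
        fields = geno.split()
        if len(fields) != len(loci):
            raise ValueError(
                f"{path}:{lineno + 1}: expected {len(loci)} genotypes, got {len(fields)}"
            )
        calls = []
        for f in fields:
            if len(f) not in (4, 6) or not f.isdigit():
                raise ValueError(f"{path}:{lineno + 1}: malformed genotype {f!r}")
            w = len(f) // 2
            calls.append((int(f[:w]), int(f[w:])))
        individuals.append(name)
        populations.append(name.split("_")[0] if "_" in name else f"pop{pop_counter}")
        raw.append(calls)
    labels: dict[str, list] = {}
    for l, locus in enumerate(loci):
        vals = sorted({c for row in raw for c in row[l] if c != 0})
        labels[locus] = vals
    alleles = np.full((len(individuals), len(loci), 2), MISSING, dtype=np.int64)
    for r, row in enumerate(raw):
        for l, (c1, c2) in enumerate(row):
            if c1 == 0 or c2 == 0:
                continue
            idx = {c: j for j, c in enumerate(labels[loci[l]])}
            alleles[r, l] = (idx[c1], idx[c2])
    return GenotypeMatrix(
        individuals=individuals,
        populations=populations,
        loci=list(loci),
        alleles=alleles,
        allele_labels=labels,
        islands=dict(islands or {}),
    )


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Native long-format table: individual, population, locus, alleles."""
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def read_genotype_table(path: str | Path, islands: dict[str, str] | None = None, encoding: str = "unique_id") -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"individual": str, "population": str, "locus": str})
    individuals = list(dict.fromkeys(df["individual"]))
    loci = list(dict.fromkeys(df["locus"]))
    pop_of = dict(zip(df["individual"], df["population"]))
    def _norm(v):
        # missing entries make pandas read integer labels as floats
        if isinstance(v, float) and v.is_integer():
            return int(v)
        return v

    labels: dict[str, list] = {}
    for locus in loci:
        sub = df[df["locus"] == locus]
        vals = sorted(
            {_norm(v) for col in ("allele1", "allele2") for v in sub[col].dropna()},
        )
        labels[locus] = vals
    alleles = np.full((len(individuals), len(loci), 2), MISSING, dtype=np.int64)
    ind_idx = {x: i for i, x in enumerate(individuals)}
    loc_idx = {x: i for i, x in enumerate(loci)}
    for row in df.itertuples(index=False):
        if pd.isna(row.allele1) or pd.isna(row.allele2):
            continue
        lidx = {v: j for j, v in enumerate(labels[row.locus])}
        alleles[ind_idx[row.individual], loc_idx[row.locus]] = (
            lidx[_norm(row.allele1)],
            lidx[_norm(row.allele2)],
        )
    return GenotypeMatrix(
        individuals=individuals,
        populations=[pop_of[i] for i in individuals],
        loci=loci,
        alleles=alleles,
        allele_labels=labels,
        encoding=encoding,
        islands=dict(islands or {}),
    )
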