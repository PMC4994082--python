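"""Collapse trimmed inserts into unique depth-annotated sequences and filter.

Three filters, applied in order, mirror the genotyping workflow this package
implements: a length window (global bounds plus an optional per-locus cap of
the longest known allele + 4 repeat units), a pooled depth floor, and a
colony-prevalence floor.  Pooling is per locus across the entire dataset, so
a sequence seen in many colonies accumulates depth jointly.  Rejected
sequences are always retained in an audit table - the programmatic
equivalent of checking the reject file by eye.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .demux import ReadAssignment
from .loci import LocusSpec

__all__ = ["SeqTally", "collapse_reads", "apply_length_filter", "apply_depth_prevalence_filters"]

Key = tuple[str, str, str]  # (site, colony, locus)


@dataclass
class SeqTally:
    """Unique sequences with read depths, per (site, colony, locus).

    ``pooled`` maps locus -> sequence -> (total_depth, n_colonies) across the
    whole dataset and is rebuilt from the per-colony counts on demand.
    """

    counts: dict[Key, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, seqs in self.counts.items():
            for seq, depth in seqs.items():
                if depth < 1:
                    raise ValueError(f"{key}: depth for {seq!r} must be >= 1")

    @property
    def pooled(self) -> dict[str, dict[str, tuple[int, int]]]:
        pooled: dict[str, dict[str, list[int]]] = defaultdict(lambda: defaultdict(lambda: [0, 0]))
        for (site, colony, locus), seqs in self.counts.items():
            for seq, depth in seqs.items():
                entry = pooled[locus][seq]
                entry[0] += depth
                entry[1] += 1
        return {
            locus: {seq: (d, c) for seq, (d, c) in seqs.items()} for locus, seqs in pooled.items()
        }

    @property
    def total_reads(self) -> int:
        return sum(d for seqs in self.counts.values() for d in seqs.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"site": site, "colony": colony, "locus": locus, "sequence": seq, "depth": depth}
            for (site, colony, locus), seqs in sorted(self.counts.items())
            for seq, depth in sorted(seqs.items())
        ]
        return pd.DataFrame(rows, columns=["site", "colony", "locus", "sequence", "depth"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "SeqTally":
        df = pd.read_csv(path, sep="\t", dtype={"site": str, "colony": str, "locus": str})
        counts: dict[Key, dict[str, int]] = defaultdict(dict)
        for row in df.itertuples(index=False):
            counts[(row.site, row.colony, row.locus)][row.sequence] = int(row.depth)
        return cls(dict(counts))


def collapse_reads(assignments: Iterable[ReadAssignment]) -> SeqTally:
    """Exact-string collapse of trimmed inserts; depth = multiplicity.

    Zero-length inserts (fully trimmed reads) are kept here and removed by
    the length filter, so read counts stay conserved through this stage.
    """
    counts: dict[Key, Counter] = defaultdict(Counter)
    for a in assignments:
        counts[(a.site, a.colony, a.locus)][a.insert] += 1
    return SeqTally({key: dict(c) for key, c in counts.items()})


def _drop(
    tally: SeqTally, reject: set[tuple[str, str]], reason_by_seq: dict[tuple[str, str], str]
) -> tuple[SeqTally, pd.DataFrame]:
    """Remove (locus, sequence) pairs everywhere; build the audit table."""
    kept: dict[Key, dict[str, int]] = {}
    rows = []
    for key, seqs in tally.counts.items():
        site, colony, locus = key
        surviving = {}
        for seq, depth in seqs.items():
            if (locus, seq) in reject:
                rows.append(
                    {
                        "site": site,
                        "colony": colony,
                        "locus": locus,
                        "sequence": seq,
                        "depth": depth,
                        "reason": reason_by_seq[(locus, seq)],
                    }
                )
            else:
                surviving[seq] = depth
        if surviving:
            kept[key] = surviving
    rejects = pd.DataFrame(rows, columns=["site", "colony", "locus", "sequence", "depth", "reason"])
    return SeqTally(kept), rejects


def apply_length_filter(
    tally: SeqTally,
    min_len: int = 15,
    max_len: int = 190,
    loci: list[LocusSpec] | None = None,
    extra_repeats: int = 4,
    rejects_path: str | Path | None = None,
) -> tuple[SeqTally, pd.DataFrame]:
    """Keep sequences with ``min_len <= length <= max_len``.

    With locus metadata, each locus additionally caps length at its longest
    known allele plus ``extra_repeats`` repeat units (stutter headroom),
    combined with the global bound by minimum.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    locus_cap = {}
    if loci:
        locus_cap = {
            l.name: min(max_len, l.max_known_length + extra_repeats * len(l.motif)) for l in loci
        }
    reject: set[tuple[str, str]] = set()
    reason: dict[tuple[str, str], str] = {}
    for locus, seqs in tally.pooled.items():
        cap = locus_cap.get(locus, max_len)
        for seq in seqs:
            if len(seq) < min_len:
                reject.add((locus, seq))
                reason[(locus, seq)] = f"length {len(seq)} < {min_len}"
            elif len(seq) > cap:
                reject.add((locus, seq))
                reason[(locus, seq)] = f"length {len(seq)} > {cap}"
    out, rejects = _drop(tally, reject, reason)
    if rejects_path is not None:
        rejects.to_csv(rejects_path, sep="\t", index=False)
    return out, rejects


def apply_depth_prevalence_filters(
    tally: SeqTally,
    min_depth: int = 10,
    min_colonies: int = 2,
    rejects_path: str | Path | None = None,
) -> tuple[SeqTally, pd.DataFrame]:
    """Drop sequences with pooled depth < ``min_depth``, then sequences seen
    in fewer than ``min_colonies`` colonies regardless of depth.

    Pooling is per locus across the entire dataset.  Raising
    ``min_colonies`` (e.g. to 11, keeping alleles present in more than ten
    colonies) reproduces the stricter "min10" dataset variants.
    """
    if min_depth < 1 or min_colonies < 1:
        raise ValueError("min_depth and min_colonies must be >= 1")
    reject: set[tuple[str, str]] = set()
    reason: dict[tuple[str, str], str] = {}
    pooled = tally.pooled
    for locus, seqs in pooled.items():
        for seq, (depth, _) in seqs.items():
            if depth < min_depth:
                reject.add((locus, seq))
                reason[(locus, seq)] = f"pooled depth {depth} < {min_depth}"
    mid, rej1 = _drop(tally, reject, reason)
    reject, reason = set(), {}
    for locus, seqs in mid.pooled.items():
        for seq, (_, ncol) in seqs.items():
            if ncol < min_colonies:
                reject.add((locus, seq))
                reason[(locus, seq)] = f"colonies {ncol} < {min_colonies}"
    out, rej2 = _drop(mid, reject, reason)
    rejects = pd.concat([rej1, rej2], ignore_index=True)
    if rejects_path is not None:
        rejects.to_csv(rejects_path, sep="\t", index=False)
    return out, rejects
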