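"""Allele calling from depth-annotated unique sequences.

The half-max rule: within a colony-locus the top-depth sequence is selected,
together with every sequence whose depth is strictly greater than half the
top depth.  One candidate means a homozygote; two, a heterozygote; more than
two are resolved either by depth (second-highest, random among ties) or by a
uniform random draw among all non-top candidates.  The random strategy is
replicated to quantify its influence downstream; replicate 0 is the
canonical analysis dataset.

Genotypes are then encoded two ways: by repeat-region length (the sequencing
analogue of fragment-length peak calling, blind to flank variation) or by
unique sequence identity (distinct sequences get distinct integer labels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix
from .strsplit import split_tandem_repeat
from .tally import SeqTally

__all__ = [
    "AlleleCall",
    "select_candidates",
    "resolve_genotype",
    "call_genotypes",
    "generate_replicate_datasets",
    "encode_alleles",
    "split_tandem_repeat",
]

Calls = dict[tuple[str, str, str], "AlleleCall"]  # (site, colony, locus) -> call


@dataclass
class AlleleCall:
    """Candidates and the resolved allele pair for one colony-locus."""

    colony: str
    locus: str
    candidates: list[tuple[str, int]]
    resolved: tuple[str, str]
    strategy: str
    replicate_id: int = 0

    @property
    def is_homozygote(self) -> bool:
        return self.resolved[0] == self.resolved[1]


def select_candidates(seq_depths: dict[str, int]) -> list[tuple[str, int]]:
    """Sequences passing the half-max-depth rule, deepest first.

    Returns every sequence whose depth is strictly greater than half the
    maximum depth (the maximum itself always qualifies; ties for the top are
    all retained).  An empty tally yields an empty list - a missing call,
    not an error.
    """
    if not seq_depths:
        return []
    top = max(seq_depths.values())
    half = top / 2.0
    cands = [(seq, d) for seq, d in seq_depths.items() if d > half]
    cands.sort(key=lambda sd: (-sd[1], sd[0]))
    return cands


def resolve_genotype(
    candidates: list[tuple[str, int]], strategy: str, rng: np.random.Generator
) -> tuple[str, str]:
    """Pick the two analysis alleles from the candidate list.

    The first allele is always (one of) the deepest candidate(s).  With more
    than two candidates the second is either the next-deepest (ties broken at
    random) or, under the random strategy, a uniform draw from all non-top
    candidates.
    """
    if strategy not in ("depth", "random"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if not candidates:
        raise ValueError("cannot resolve an empty candidate list")
    if len(candidates) == 1:
        seq = candidates[0][0]
        return (seq, seq)
    top_depth = candidates[0][1]
    top_group = [sd for sd in candidates if sd[1] == top_depth]
    a1 = top_group[int(rng.integers(len(top_group)))][0]
    rest = [sd for sd in candidates if sd[0] != a1]
    if strategy == "depth":
        second_depth = max(d for _, d in rest)
        pool = [s for s, d in rest if d == second_depth]
    else:
        pool = [s for s, _ in rest]
    a2 = pool[int(rng.integers(len(pool)))]
    return (a1, a2)


def call_genotypes(
    tally: SeqTally, strategy: str = "random", rng: np.random.Generator | None = None, replicate_id: int = 0
) -> Calls:
    """Apply the half-max rule and resolution to every colony-locus."""
    rng = np.random.default_rng(0) if rng is None else rng
    calls: Calls = {}
    for key in sorted(tally.counts):
        site, colony, locus = key
        cands = select_candidates(tally.counts[key])
        if not cands:
            continue
        resolved = resolve_genotype(cands, strategy, rng)
        calls[key] = AlleleCall(colony, locus, cands, resolved, strategy, replicate_id)
    return calls


def generate_replicate_datasets(
    tally: SeqTally, k: int = 10, seed: int = 0, seeds: list[int] | None = None
) -> list[Calls]:
    """k independent random-strategy resolutions of the same tally.

    Replicates differ only at colony-loci with more than two candidates.
    Replicate 0 is the canonical analysis dataset.  Each replicate has its
    own deterministic child seed, so any one can be regenerated alone.
    """
    if seeds is not None and len(seeds) != k:
        raise ValueError("seeds must have length k")
    out = []
    for rep in range(k):
        s = seeds[rep] if seeds is not None else np.random.SeedSequence([seed, rep]).generate_state(1)[0]
        rng = np.random.default_rng(s)
        out.append(call_genotypes(tally, "random", rng, replicate_id=rep))
    return out


def encode_alleles(
    calls: Calls,
    mode: str = "unique_id",
    islands: dict[str, str] | None = None,
    individuals: list[tuple[str, str]] | None = None,
    loci: list[str] | None = None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix labelling alleles by length or by identity.

    ``length`` labels an allele by its repeat-region length (same-length
    alleles merge regardless of sequence); ``unique_id`` gives every distinct
    sequence its own integer label.  A sequence with no detectable tandem
    repeat cannot be length-encoded: the whole call becomes missing.
    """
    if mode not in ("length", "unique_id"):
        raise ValueError(f"unknown encoding {mode!r}")
    if individuals is None:
        individuals = sorted({(site, colony) for site, colony, _ in calls})
    if loci is None:
        loci = sorted({locus for _, _, locus in calls})

    def label_of(seq: str):
        if mode == "unique_id":
            return seq
        res = split_tandem_repeat(seq)
        return res.repeat_length if res.found else None

    labels: dict[str, list] = {}
    for locus in loci:
        vals = set()
        for (s, c, l), call in calls.items():
            if l != locus:
                continue
            for seq in call.resolved:
                lab = label_of(seq)
                if lab is not None:
                    vals.add(lab)
        labels[locus] = sorted(vals)
    if mode == "unique_id":
        # persistable integer identities, assigned in sorted-sequence order
        seq_order = {l: {seq: i for i, seq in enumerate(labels[l])} for l in loci}
        labels = {l: list(range(1, len(labels[l]) + 1)) for l in loci}

    n, L = len(individuals), len(loci)
    alleles = np.full((n, L, 2), MISSING, dtype=np.int64)
    index = {l: {lab: i for i, lab in enumerate(labels[l])} for l in loci}
    ind_idx = {ic: i for i, ic in enumerate(individuals)}
    loc_idx = {l: i for i, l in enumerate(loci)}
    for (site, colony, locus), call in calls.items():
        if (site, colony) not in ind_idx or locus not in loc_idx:
            continue
        pair = []
        for seq in call.resolved:
            if mode == "unique_id":
                pair.append(index[locus][seq_order[locus][seq] + 1])
            else:
                lab = label_of(seq)
                if lab is None:
                    pair = []
                    break
                pair.append(index[locus][lab])
        if len(pair) == 2:
            alleles[ind_idx[(site, colony)], loc_idx[locus]] = pair
    return GenotypeMatrix(
        individuals=[f"{s}_{c}" for s, c in individuals],
        populations=[s for s, _ in individuals],
        loci=list(loci),
        alleles=alleles,
        allele_labels=labels,
        encoding=mode,
        islands=dict(islands or {}),
    )
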