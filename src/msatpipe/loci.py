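"""Locus and barcode metadata.

A sequenced microsatellite amplicon has the layout::

    siteID - colonyID - FWDprimer - left_flank - (motif * k) - right_flank - RVSprimer

``LocusSpec`` records everything needed to build, demultiplex and interpret
one locus; ``BarcodeScheme`` holds the inline site and colony tags.  The
default scheme mirrors the study design this package emulates: seven reef
sites on three island groups, up to 48 tagged colonies per site, and eleven
scorable microsatellite loci.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .strsplit import MAX_MOTIF, MIN_MOTIF, split_tandem_repeat

BASES = "ACGT"

#: Site -> island assignment of the emulated sampling design.
DEFAULT_ISLANDS: dict[str, str] = {
    "S17": "Palau",
    "S20": "Palau",
    "S24": "Palau",
    "S27": "Yap",
    "S29": "Yap",
    "S30": "Yap",
    "S28": "Ngulu",
}

#: Colonies genotyped per site in the emulated design.
DEFAULT_POP_SIZES: dict[str, int] = {
    "S17": 48,
    "S20": 48,
    "S24": 48,
    "S27": 37,
    "S29": 48,
    "S30": 48,
    "S28": 43,
}


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class LocusSpec:
    """Primers, flanks and repeat structure of one microsatellite locus."""

    name: str
    fwd_primer: str
    rvs_primer: str
    left_flank: str
    right_flank: str
    motif: str
    repeat_range: tuple[int, int]
    max_known_length: int

    def __post_init__(self) -> None:
        if not (MIN_MOTIF <= len(self.motif) <= MAX_MOTIF):
            raise ValueError(f"{self.name}: motif length must be in [{MIN_MOTIF}, {MAX_MOTIF}]")
        lo, hi = self.repeat_range
        if lo < 3:
            raise ValueError(f"{self.name}: minimum repeat count must be >= 3")
        if hi < lo:
            raise ValueError(f"{self.name}: repeat_range must be (min, max) with max >= min")
        for side, flank in (("left", self.left_flank), ("right", self.right_flank)):
            if self.motif in flank:
                raise ValueError(
                    f"{self.name}: {side} flank contains a full copy of motif {self.motif!r}"
                )

    @property
    def flank_length(self) -> int:
        return len(self.left_flank) + len(self.right_flank)

    def insert_length(self, repeats: int) -> int:
        return self.flank_length + repeats * len(self.motif)


@dataclass(frozen=True)
class BarcodeScheme:
    """Inline tags: one per site plus 48 colony IDs shared across sites."""

    site_tags: dict[str, str]
    colony_tags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for tier, tags in (("site", list(self.site_tags.values())), ("colony", list(self.colony_tags))):
            if len(set(tags)) != len(tags):
                raise ValueError(f"duplicate {tier} tags")
            if any(len(t) < 1 for t in tags):
                raise ValueError(f"{tier} tag shorter than 1 nt")
            for a, b in itertools.combinations(tags, 2):
                if hamming(a, b) < 2:
                    raise ValueError(f"{tier} tags {a!r}/{b!r} closer than Hamming 2")

    @property
    def n_colonies(self) -> int:
        return len(self.colony_tags)


def _parity_code(length: int = 5) -> list[str]:
    """All DNA words of the given length whose base indices sum to 0 mod 4.

    A single-parity-check code over GF(4): any two codewords differ in at
    least two positions, so one substitution never converts one tag into
    another.
    """
    words = []
    for combo in itertools.product(range(4), repeat=length - 1):
        check = (-sum(combo)) % 4
        word = "".join(BASES[i] for i in combo) + BASES[check]
        words.append(word)
    return words


def default_barcode_scheme(sites: list[str] | None = None, n_colonies: int = 48) -> BarcodeScheme:
    """Deterministic tag sets drawn from a distance-2 parity-check code."""
    sites = list(DEFAULT_ISLANDS) if sites is None else list(sites)
    code = _parity_code(5)
    colony_tags = tuple(code[:n_colonies])
    site_words = code[n_colonies : n_colonies + len(sites)]
    return BarcodeScheme(site_tags=dict(zip(sites, site_words)), colony_tags=colony_tags)


_DEFAULT_MOTIFS = [
    "AC", "AG", "AAG", "ATC", "AT", "ACG", "AAT", "ACAG", "AATG", "CA", "AGG",
    "AAAC", "GA", "ACT", "AGAT", "CT", "AATC", "TG",
]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _flank_ok(locus: LocusSpec) -> bool:
    """Round-trip check: the tandem-repeat splitter must recover exactly the
    simulated repeat region at both ends of the repeat range (flank bases must
    not extend the periodic run)."""
    for reps in (locus.repeat_range[0], locus.repeat_range[1]):
        seq = locus.left_flank + locus.motif * reps + locus.right_flank
        res = split_tandem_repeat(seq)
        if res.repeat_region != locus.motif * reps or res.left_flank != locus.left_flank:
            return False
    return True


def default_loci(n_loci: int = 11, max_insert: int = 190, seed: int = 20160818) -> list[LocusSpec]:
    """Deterministically generated locus panel.

    Motifs cycle over common di- to tetranucleotide repeats; flanks and
    primers are random but validated so that (i) primers are mutually
    distant enough for mismatch-tolerant matching, and (ii) flanks neither
    contain the motif nor extend the tandem run, keeping repeat-region
    detection exact for error-free sequences.
    """
    rng = np.random.default_rng(seed)
    loci: list[LocusSpec] = []
    primers: list[str] = []
    for i in range(n_loci):
        motif = _DEFAULT_MOTIFS[i % len(_DEFAULT_MOTIFS)]
        m = len(motif)
        lo = 5
        for _ in range(200):
            left = _random_dna(rng, int(rng.integers(16, 25)))
            right = _random_dna(rng, int(rng.integers(16, 25)))
            hi_cap = (max_insert - len(left) - len(right)) // m
            hi = min(lo + int(rng.integers(12, 30)), hi_cap)
            if hi < lo + 4:
                continue
            try:
                locus = LocusSpec(
                    name=f"loc{i + 1}",
                    fwd_primer="",
                    rvs_primer="",
                    left_flank=left,
                    right_flank=right,
                    motif=motif,
                    repeat_range=(lo, hi),
                    max_known_length=len(left) + len(right) + hi * m,
                )
            except ValueError:
                continue
            if _flank_ok(locus):
                break
        else:  # pragma: no cover - generation is deterministic and succeeds
            raise RuntimeError(f"could not build flanks for motif {motif}")
        while True:
            fwd = _random_dna(rng, 20)
            rvs = _random_dna(rng, 20)
            if all(hamming(fwd, p) >= 6 for p in primers):
                break
        primers.append(fwd)
        loci.append(
            LocusSpec(
                name=locus.name,
                fwd_primer=fwd,
                rvs_primer=rvs,
                left_flank=locus.left_flank,
                right_flank=locus.right_flank,
                motif=motif,
                repeat_range=locus.repeat_range,
                max_known_length=locus.max_known_length,
            )
        )
    return loci
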