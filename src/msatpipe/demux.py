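"""Demultiplexing and quality trimming of merged amplicon reads.

A single auditable stage replaces the usual three-tool chain (vendor
demultiplexer, inline-barcode groomer, quality trimmer): reads are assigned
to (site, colony, locus) by exact site and colony tags followed by a
mismatch-tolerant forward-primer match, then the reverse primer and any
low-quality tail are trimmed, leaving the bare insert
(flank + tandem repeat + flank).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .loci import BarcodeScheme, LocusSpec

PHRED_OFFSET = 33

__all__ = ["ReadAssignment", "demultiplex_reads", "trim_read", "merge_pair", "iter_fastq"]


@dataclass(frozen=True)
class ReadAssignment:
    """One read assigned to (site, colony, locus), with tags/primer stripped."""

    site: str
    colony: str
    locus: str
    insert: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.insert) != len(self.qualities):
            raise ValueError("insert and qualities length mismatch")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a FASTQ file (gzip aware).

    Malformed records raise a parse error naming the index of the failing
    record.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record at index {index} in {path}: {exc}") from exc
            yield rec
            index += 1


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex_reads(
    reads: Iterable[tuple[str, str, str]] | str | Path,
    scheme: BarcodeScheme,
    loci: list[LocusSpec],
    max_mismatch: int = 2,
) -> tuple[list[ReadAssignment], list[tuple[str, str, str]], dict]:
    """Assign reads by site tag, colony tag, then forward primer.

    Site and colony tags must match exactly; the forward primer may carry up
    to ``max_mismatch`` substitutions, ties resolved by fewest mismatches and
    ambiguous ties left unassigned.  Returns assignments, the unassigned
    reads, and per-(site, locus) assigned counts plus per-site unassigned
    counts under the key ``("unassigned", site)``; reads failing the site tag
    count under ``("unassigned", "?")``.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if not loci:
        raise ValueError("no loci given")
    if isinstance(reads, (str, Path)):
        reads = iter_fastq(reads)
    site_by_tag = {tag: site for site, tag in scheme.site_tags.items()}
    site_len = {len(tag) for tag in scheme.site_tags.values()}
    colony_by_tag = {tag: f"c{i:02d}" for i, tag in enumerate(scheme.colony_tags)}
    colony_len = {len(t) for t in scheme.colony_tags}
    if len(site_len) != 1 or len(colony_len) != 1:
        raise ValueError("tags must have uniform length within a tier")
    slen, clen = site_len.pop(), colony_len.pop()
    primer_exact = {locus.fwd_primer: locus for locus in loci}
    primer_lens = {len(p) for p in primer_exact}
    # exact-lookup fast path only works when all primers share one length
    uniform_plen = primer_lens.pop() if len(primer_lens) == 1 else 0

    assigned: list[ReadAssignment] = []
    unassigned: list[tuple[str, str, str]] = []
    counts: dict[tuple[str, str], int] = {}

    def _fail(site_label: str, rec: tuple[str, str, str]) -> None:
        unassigned.append(rec)
        key = ("unassigned", site_label)
        counts[key] = counts.get(key, 0) + 1

    for rec in reads:
        rid, seq, qual = rec
        site = site_by_tag.get(seq[:slen])
        if site is None:
            _fail("?", rec)
            continue
        colony = colony_by_tag.get(seq[slen : slen + clen])
        if colony is None:
            _fail(site, rec)
            continue
        body = seq[slen + clen :]
        best: LocusSpec | None = primer_exact.get(body[:uniform_plen]) if uniform_plen else None
        if best is None:
            best_mm = max_mismatch + 1
            tie = False
            for cand in loci:
                if len(body) < len(cand.fwd_primer):
                    continue
                mm = _mismatches(body[: len(cand.fwd_primer)], cand.fwd_primer)
                if mm < best_mm:
                    best_mm, best, tie = mm, cand, False
                elif mm == best_mm:
                    tie = True
            if best is None or best_mm > max_mismatch or tie:
                _fail(site, rec)
                continue
        plen = len(best.fwd_primer)
        insert = body[plen:]
        qinsert = qual[slen + clen + plen :]
        assigned.append(ReadAssignment(site, colony, best.name, insert, qinsert))
        key = (site, best.name)
        counts[key] = counts.get(key, 0) + 1
    return assigned, unassigned, counts


def _find_primer(insert: str, primer: str, max_mismatch: int) -> int:
    """Leftmost start of the reverse primer within the insert, -1 if absent."""
    pos = insert.find(primer)
    if pos >= 0:
        return pos
    if max_mismatch == 0 or len(insert) < len(primer):
        return -1
    arr = np.frombuffer(insert.encode("ascii"), dtype=np.uint8)
    parr = np.frombuffer(primer.encode("ascii"), dtype=np.uint8)
    L, P = arr.size, parr.size
    windows = np.lib.stride_tricks.sliding_window_view(arr, P)
    mism = (windows != parr).sum(axis=1)
    hits = np.nonzero(mism <= max_mismatch)[0]
    return int(hits[0]) if hits.size else -1


def trim_read(
    assignment: ReadAssignment,
    rvs_primer: str,
    window: int = 4,
    min_quality: float = 15.0,
    max_mismatch: int = 2,
) -> ReadAssignment:
    """Remove the reverse primer (and everything after it), then truncate at
    the first sliding window whose mean quality drops below the threshold.

    Fully trimmed reads come back with a zero-length insert; the length
    filter downstream is responsible for discarding them.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    insert, qual = assignment.insert, assignment.qualities
    if rvs_primer:
        pos = _find_primer(insert, rvs_primer, max_mismatch)
        if pos >= 0:
            insert, qual = insert[:pos], qual[:pos]
    if insert:
        scores = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(float) - PHRED_OFFSET
        if scores.size >= window:
            means = np.convolve(scores, np.ones(window) / window, mode="valid")
            bad = np.nonzero(means < min_quality)[0]
            if bad.size:
                cut = int(bad[0])
                insert, qual = insert[:cut], qual[:cut]
        elif scores.size and scores.mean() < min_quality:
            insert, qual = "", ""
    return replace(assignment, insert=insert, qualities=qual)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def merge_pair(
    fwd: tuple[str, str], rev: tuple[str, str], min_overlap: int = 10, min_identity: float = 0.9
) -> tuple[str, str] | None:
    """Naive overlap merger for paired reads (convenience plumbing only; the
    supported input is pre-merged reads).  ``rev`` is reverse-complemented,
    the highest-identity overlap of at least ``min_overlap`` bases is taken,
    and overlapping bases keep the higher-quality call."""
    fseq, fqual = fwd
    rseq = rev[0].translate(_COMPLEMENT)[::-1]
    rqual = rev[1][::-1]
    best = None
    for ov in range(min(len(fseq), len(rseq)), min_overlap - 1, -1):
        a, b = fseq[-ov:], rseq[:ov]
        ident = sum(x == y for x, y in zip(a, b)) / ov
        if ident >= min_identity:
            best = ov
            break
    if best is None:
        return None
    merged, qual = list(fseq[: len(fseq) - best]), list(fqual[: len(fseq) - best])
    for i in range(best):
        fi = len(fseq) - best + i
        if ord(fqual[fi]) >= ord(rqual[i]):
            merged.append(fseq[fi])
            qual.append(fqual[fi])
        else:
            merged.append(rseq[i])
            qual.append(rqual[i])
    merged += list(rseq[best:])
    qual += list(rqual[best:])
    return "".join(merged), "".join(qual)
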