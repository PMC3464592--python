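"""Shotgun-assembly collapse simulation for near-identical paralogs.

A reference sequence is fragmented into fixed-length error-free reads at a
target fold coverage, reassembled with a deterministic greedy
overlap-layout assembler, and the contigs are mapped back to the
reference.  Identical repeat copies longer than the read length cannot be
separated by suffix-prefix overlaps and co-assemble into a single contig
— the collapse events this module detects.
"""

from __future__ import annotations

import heapq
import random
from dataclasses import dataclass, field

import edlib


@dataclass
class ReadSet:
    reads: list[str]
    read_length: int
    coverage: float
    seed: int


@dataclass
class ContigMapping:
    contigs: list[str]
    mapped: list[bool]
    identities: list[float]
    mapped_fraction: float
    collapse_events: int = 0
    reference_covered_fraction: float | None = None


def fragment(reference: str, read_length: int = 500, coverage: float = 10.0,
             seed: int = 0) -> ReadSet:
    """Sample N = round(coverage * L / read_length) error-free reads.

    Start positions are uniform over the reference (forward strand only);
    the same seed reproduces the identical read set.
    """
    L = len(reference)
    if L < read_length:
        raise ValueError("reference shorter than the read length")
    n_reads = round(coverage * L / read_length)
    rng = random.Random(seed)
    reads = []
    for _ in range(n_reads):
        start = rng.randrange(0, L - read_length + 1)
        reads.append(reference[start:start + read_length])
    return ReadSet(reads=reads, read_length=read_length, coverage=coverage, seed=seed)


def _suffix_prefix_overlaps(seqs: list[str], min_overlap: int):
    """All (overlap, i, j) with suffix of seqs[i] == prefix of seqs[j], i != j."""
    by_prefix: dict[str, list[int]] = {}
    for j, s in enumerate(seqs):
        by_prefix.setdefault(s[:min_overlap], []).append(j)
    overlaps = []
    for i, s in enumerate(seqs):
        seen: set[int] = set()
        for start in range(max(0, len(s) - min_overlap), -1, -1):
            seed = s[start:start + min_overlap]
            for j in by_prefix.get(seed, ()):
                if j == i or j in seen:
                    continue
                ov = len(s) - start
                if ov <= len(seqs[j]) and seqs[j].startswith(s[start:]):
                    overlaps.append((ov, i, j))
                    seen.add(j)
    return overlaps


def greedy_assemble(reads: list[str], min_overlap: int = 50) -> list[str]:
    """Deterministic greedy overlap assembly of error-free reads.

    Repeatedly merges the pair with the longest exact suffix-prefix overlap
    of at least ``min_overlap`` (ties broken lexicographically on the read
    order key), until no merge is possible.  Duplicate reads and contigs
    contained inside another contig are absorbed.
    """
    seqs = sorted(set(reads))
    if not seqs:
        return []
    heap = [(-ov, i, j) for ov, i, j in _suffix_prefix_overlaps(seqs, min_overlap)]
    heapq.heapify(heap)
    # contig state: chains of read indices; head/tail record which original
    # read currently forms each contig's prefix/suffix
    next_right: dict[int, int] = {}
    prev_left: dict[int, int] = {}
    shift: dict[int, int] = {}  # offset of each read within its chain
    while heap:
        neg_ov, i, j = heapq.heappop(heap)
        if i in next_right or j in prev_left:
            continue  # an end already consumed by a better merge
        # reject merges that would close a circle
        k = j
        while k in next_right:
            k = next_right[k]
        if k == i:
            continue
        next_right[i] = j
        prev_left[j] = i
        shift[j] = len(seqs[i]) + neg_ov  # neg_ov = -overlap
    contigs = []
    heads = [i for i in range(len(seqs)) if i not in prev_left]
    for head in sorted(heads):
        contig = seqs[head]
        k = head
        while k in next_right:
            nxt = next_right[k]
            ov = len(seqs[k]) - (shift[nxt])
            contig += seqs[nxt][ov:]
            k = nxt
        contigs.append(contig)
    # absorb contigs contained in a longer contig
    contigs.sort(key=lambda c: (-len(c), c))
    kept: list[str] = []
    for c in contigs:
        if not any(c in other for other in kept):
            kept.append(c)
    return sorted(kept)


def map_contigs(contigs: list[str], reference: str, min_identity: float = 0.98,
                repeats: list[tuple[str, int]] | None = None) -> ContigMapping:
    """Map each contig back to the reference by banded edit-distance search.

    A contig maps when its best infix alignment to the reference reaches
    ``min_identity`` over its full length.  ``repeats`` is an optional list
    of (repeat_sequence, n_planted_copies); a collapse event is recorded
    for every planted copy beyond the number of distinct contig occurrences
    of that repeat.
    """
    mapped = []
    identities = []
    for contig in contigs:
        res = edlib.align(contig, reference, mode="HW", task="distance")
        identity = 1.0 - res["editDistance"] / len(contig)
        identities.append(identity)
        mapped.append(identity >= min_identity)
    fraction = sum(mapped) / len(contigs) if contigs else 0.0
    collapse = 0
    if repeats:
        for repeat_seq, n_copies in repeats:
            max_dist = max(1, int(round((1 - min_identity) * len(repeat_seq))))
            occurrences = 0
            for contig in contigs:
                if len(contig) < len(repeat_seq):
                    continue
                res = edlib.align(repeat_seq, contig, mode="HW", task="locations",
                                  k=max_dist)
                if res["editDistance"] != -1:
                    # count non-overlapping hits within this contig
                    locs = sorted(set(res["locations"]))
                    last_end = -1
                    for start, end in locs:
                        if start is None:
                            start = 0
                        if start > last_end:
                            occurrences += 1
                            last_end = end
            collapse += max(0, n_copies - occurrences)
    covered = _reference_coverage(contigs, reference, min_identity)
    return ContigMapping(contigs=contigs, mapped=mapped, identities=identities,
                         mapped_fraction=fraction, collapse_events=collapse,
                         reference_covered_fraction=covered)


def _reference_coverage(contigs: list[str], reference: str,
                        min_identity: float) -> float:
    """Fraction of reference bases covered by mapped contig intervals."""
    intervals = []
    for contig in contigs:
        res = edlib.align(contig, reference, mode="HW", task="locations")
        if res["editDistance"] / len(contig) > 1 - min_identity:
            continue
        for start, end in res["locations"]:
            intervals.append((start or 0, end))
    if not intervals:
        return 0.0
    intervals.sort()
    covered = 0
    cur_start, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start <= cur_end + 1:
            cur_end = max(cur_end, end)
        else:
            covered += cur_end - cur_start + 1
            cur_start, cur_end = start, end
    covered += cur_end - cur_start + 1
    return covered / len(reference)
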