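"""Mismatch-bounded exhaustive short-read alignment, best stratum, all hits.

Semantics mirror the classic ungapped end-to-end short-read contract
``-v <m> -a --best --strata [--norc]``: among all end-to-end placements of
the query (both strands unless ``sense_only``) with at most ``max_mismatch``
mismatches, report every placement achieving the minimal mismatch count.
``N`` on either side always counts as a mismatch, so N-containing reads can
never align exactly.

Completeness comes from pigeonhole seeding: a placement with at most m
mismatches must contain a mismatch-free block when the query is split into
m+1 blocks, and the k-mer at that block's start is then an exact index hit.
Queries too short to carry m+1 disjoint k-seeds fall back to a full scan.
Every candidate is verified by recounting mismatches, so seeding can only
miss, never invent, hits — and the block partition guarantees it never
misses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .smallrna import CollapsedRead, normalize_sequence, revcomp

__all__ = ["TargetIndex", "Hit", "build_index", "align"]


@dataclass(frozen=True, order=True)
class Hit:
    """One end-to-end placement of a query on a target."""

    query_id: str
    target_id: str
    start: int  # 0-based on target forward strand
    strand: str  # '+' or '-'
    mismatches: int


@dataclass
class TargetIndex:
    """Named target sequences plus an exact k-mer lookup table."""

    targets: dict[str, str]
    k: int
    lookup: dict[str, list[tuple[str, int]]] = field(repr=False)


def build_index(targets: Mapping[str, str] | Iterable[tuple[str, str]], k: int = 6) -> TargetIndex:
    """Index every length-k substring of every target."""
    tdict = dict(targets)
    if not tdict:
        raise ValueError("empty target list")
    if k < 4:
        raise ValueError("k must be >= 4")
    tdict = {tid: normalize_sequence(seq) for tid, seq in tdict.items()}
    shortest = min(len(s) for s in tdict.values())
    if k > shortest:
        raise ValueError(f"k={k} longer than shortest target ({shortest} nt)")
    lookup: dict[str, list[tuple[str, int]]] = {}
    for tid, seq in tdict.items():
        for off in range(len(seq) - k + 1):
            lookup.setdefault(seq[off : off + k], []).append((tid, off))
    return TargetIndex(tdict, k, lookup)


def _count_mismatches(a: str, b: str, limit: int) -> int:
    """Hamming distance with N counting as mismatch; early exit past limit."""
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


def _candidate_starts(q: str, index: TargetIndex, m: int) -> set[tuple[str, int]]:
    k = index.k
    L = len(q)
    cands: set[tuple[str, int]] = set()
    if L >= (m + 1) * k:
        # m+1 evenly-spread seed blocks; each block is at least k long.
        bounds = [round(i * L / (m + 1)) for i in range(m + 2)]
        for b in range(m + 1):
            s = bounds[b]
            seed = q[s : s + k]
            for tid, off in index.lookup.get(seed, ()):
                start = off - s
                if 0 <= start <= len(index.targets[tid]) - L:
                    cands.add((tid, start))
    else:
        for tid, t in index.targets.items():
            cands.update((tid, start) for start in range(len(t) - L + 1))
    return cands


def align(
    query: CollapsedRead | str,
    index: TargetIndex,
    max_mismatch: int = 1,
    sense_only: bool = False,
    query_id: str | None = None,
) -> list[Hit]:
    """All best-stratum end-to-end placements of ``query`` on the index.

    Returns the empty list when no placement fits within ``max_mismatch``.
    Output order is deterministic: (target_id, start, strand).
    """
    if isinstance(query, CollapsedRead):
        qid = query_id or query.tag_id
        qseq = query.sequence
    else:
        qid = query_id or "query"
        qseq = normalize_sequence(query)
    if len(qseq) < index.k:
        raise ValueError(f"query shorter than seed length k={index.k}")

    strands = [("+", qseq)] if sense_only else [("+", qseq), ("-", revcomp(qseq))]
    hits: list[Hit] = []
    best = max_mismatch
    for strand, q in strands:
        for tid, start in _candidate_starts(q, index, max_mismatch):
            mm = _count_mismatches(q, index.targets[tid][start : start + len(q)], max_mismatch)
            if mm <= max_mismatch:
                hits.append(Hit(qid, tid, start, strand, mm))
                best = min(best, mm)
    hits = [h for h in hits if h.mismatches == best]
    hits.sort(key=lambda h: (h.target_id, h.start, h.strand))
    return hits


def align_many(
    queries: Sequence[CollapsedRead],
    index: TargetIndex,
    max_mismatch: int = 1,
    sense_only: bool = False,
) -> dict[str, list[Hit]]:
    """Map tag_id -> best-stratum hits for a whole collapsed library."""
    return {
        q.tag_id: align(q, index, max_mismatch=max_mismatch, sense_only=sense_only)
        for q in queries
    }
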