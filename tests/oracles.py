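"""Independent oracles used by the unit tests and the acceptance script.

Each oracle recomputes a result by a route deliberately different from the
package implementation: brute-force scans, exhaustive enumeration, or
direct per-column bookkeeping.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Brute-force best-stratum short-read alignment (numpy Hamming scan)
# ---------------------------------------------------------------------------

_ENC = {b: i for i, b in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def brute_force_hits(
    query: str, targets: dict[str, str], max_mismatch: int, sense_only: bool = False
) -> list[tuple[str, str, int, str, int]]:
    """All best-stratum end-to-end placements by scanning every offset and
    strand with a vectorized Hamming count (N always mismatches).

    Returns (query_id='query', target_id, start, strand, mismatches)
    sorted like the implementation.
    """
    L = len(query)
    n_char = ord("N")
    raw: list[tuple[str, int, str, int]] = []
    strands = [("+", query)] if sense_only else [("+", query), ("-", revcomp(query))]
    for tid, t in targets.items():
        if len(t) < L:
            continue
        enc_t = _encode(t)
        windows = np.lib.stride_tricks.sliding_window_view(enc_t, L)
        for strand, q in strands:
            enc_q = _encode(q)
            mm = (
                (windows != enc_q) | (windows == n_char) | (enc_q == n_char)
            ).sum(axis=1)
            for start in np.nonzero(mm <= max_mismatch)[0]:
                raw.append((tid, int(start), strand, int(mm[start])))
    if not raw:
        return []
    best = min(r[3] for r in raw)
    hits = [("query", tid, s, st, m) for tid, s, st, m in raw if m == best]
    hits.sort(key=lambda h: (h[1], h[2], h[3]))
    return hits


# ---------------------------------------------------------------------------
# Per-column MAF slice scan
# ---------------------------------------------------------------------------

def reference_chars_in_region(blocks, start: int, end: int, chrom: str) -> str:
    """Reference characters inside [start, end) by scanning every column of
    every block and tracking the running reference coordinate."""
    out = []
    for block in blocks:
        ref = block.rows[0]
        if ref.chrom != chrom:
            continue
        pos = ref.start
        for ch in ref.text:
            if ch != "-":
                if start <= pos < end:
                    out.append(ch)
                pos += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# Exhaustive enumeration of non-crossing RNA structures
# ---------------------------------------------------------------------------

_PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}


def enumerate_structures(seq: str, min_loop: int = 3):
    """Yield every non-crossing pair set (as a frozenset) over seq."""

    def rec(positions: tuple[int, ...]):
        if not positions:
            yield frozenset()
            return
        i, rest = positions[0], positions[1:]
        # i unpaired
        for s in rec(rest):
            yield s
        # i paired with any admissible k (non-crossing via interval split)
        for idx, k in enumerate(rest):
            if k - i - 1 < min_loop:
                continue
            if _PAIR_WEIGHT.get((seq[i], seq[k])) is None:
                continue
            inside = tuple(p for p in rest[:idx] if i < p < k)
            outside = tuple(p for p in rest[idx + 1 :])
            for s_in in rec(inside):
                for s_out in rec(outside):
                    yield s_in | s_out | {(i, k)}

    seen = set()
    for s in rec(tuple(range(len(seq)))):
        if s not in seen:
            seen.add(s)
            yield s


def best_structure_score(seq: str, min_loop: int = 3) -> int:
    """Maximum total pair weight over all enumerated structures."""
    best = 0
    for s in enumerate_structures(seq, min_loop):
        score = sum(_PAIR_WEIGHT[(seq[i], seq[j])] for i, j in s)
        if score > best:
            best = score
    return best
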