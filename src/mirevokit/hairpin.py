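"""Hairpin secondary structure: weighted-pair folding DP, structure
projection onto alignments, per-base read coverage, plausibility filter.

Folding maximizes a base-pair weight sum (GC=3, AU=2, GU=1) over
non-crossing structures with a minimum hairpin loop of 3 nt — a
Nussinov-style dynamic programme, not a thermodynamic nearest-neighbour
model. It is a deliberately simple, fully deterministic stand-in: an
externally computed dot-bracket string (e.g. from an MFE folder) can be
supplied anywhere a FoldResult is accepted, via :func:`fold_from_bracket`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .annotate import PrecursorAnnotation
from .smallrna import normalize_sequence

__all__ = [
    "FoldResult",
    "HairpinProfile",
    "HairpinParams",
    "PRESETS",
    "fold",
    "fold_from_bracket",
    "project_structure",
    "hairpin_coverage",
    "hairpin_filter",
]

MIN_LOOP = 3
_PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}


@dataclass(frozen=True)
class FoldResult:
    sequence: str
    dot_bracket: str
    score: int
    pairs: tuple[tuple[int, int], ...]  # 0-based (i, j), i < j

    def paired_positions(self) -> set[int]:
        return {i for p in self.pairs for i in p}


@dataclass(frozen=True)
class HairpinProfile:
    precursor_id: str
    coverage: tuple[int, ...]


def _weight(a: str, b: str) -> int:
    return _PAIR_WEIGHT.get((a, b), 0)


def fold(sequence: str) -> FoldResult:
    """Maximum-weight non-crossing structure with min loop 3.

    Traceback is deterministic: at each subproblem [i, j], pairing (i, j)
    itself is preferred, then partners k in ascending order, then leaving
    i unpaired; co-optimal structures therefore resolve the same way on
    every run.
    """
    seq = normalize_sequence(sequence)
    n = len(seq)
    # W[i][j]: best weight on seq[i..j] inclusive
    W = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = W[i + 1][j]  # i unpaired
            for k in range(i + MIN_LOOP + 1, j + 1):
                w = _weight(seq[i], seq[k])
                if w == 0:
                    continue
                cand = w + (W[i + 1][k - 1] if k - 1 > i + 1 else 0)
                if k + 1 <= j:
                    cand += W[k + 1][j]
                if cand > best:
                    best = cand
            W[i][j] = best
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i < MIN_LOOP + 1:
            continue
        target = W[i][j]
        # prefer pairing (i, j) itself, then partners k ascending, then i unpaired
        chosen = None
        for k in (j, *range(i + MIN_LOOP + 1, j)):
            w = _weight(seq[i], seq[k])
            if w == 0:
                continue
            cand = w + (W[i + 1][k - 1] if k - 1 > i + 1 else 0)
            if k + 1 <= j:
                cand += W[k + 1][j]
            if cand == target:
                chosen = k
                break
        if chosen is not None:
            pairs.append((i, chosen))
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))
        else:
            stack.append((i + 1, j))
    pairs.sort()
    brackets = ["."] * n
    for i, j in pairs:
        brackets[i], brackets[j] = "(", ")"
    score = sum(_weight(seq[i], seq[j]) for i, j in pairs)
    return FoldResult(seq, "".join(brackets), score, tuple(pairs))


def fold_from_bracket(sequence: str, dot_bracket: str) -> FoldResult:
    """Wrap an externally computed dot-bracket string as a FoldResult."""
    seq = normalize_sequence(sequence)
    if len(seq) != len(dot_bracket):
        raise ValueError("sequence and dot-bracket lengths differ")
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(dot_bracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"invalid bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced '(' remaining")
    pairs.sort()
    score = sum(_weight(seq[i], seq[j]) for i, j in pairs)
    return FoldResult(seq, dot_bracket, score, tuple(pairs))


def project_structure(
    homologs, folds: Mapping[str, FoldResult]
) -> dict[str, str]:
    """Align bracket strings to a homolog alignment by re-inserting '-' at
    each species' gap columns; removing the gaps restores the original."""
    out = {}
    for species, fr in folds.items():
        gapped = homologs.rows[species]
        brackets = iter(fr.dot_bracket)
        projected = []
        for ch in gapped:
            projected.append("-" if ch == "-" else next(brackets))
        leftover = sum(1 for _ in brackets)
        if leftover:
            raise ValueError(
                f"{species}: structure length exceeds ungapped row by {leftover}"
            )
        if len(fr.dot_bracket) != len(gapped) - gapped.count("-"):
            raise ValueError(f"{species}: structure/row length mismatch")
        out[species] = "".join(projected)
    return out


def hairpin_coverage(
    annot: PrecursorAnnotation,
    hits: Sequence[tuple[int, int, int]],
) -> HairpinProfile:
    """Per-base read coverage over the precursor.

    ``hits`` are (start, read_length, collapsed_count) on the sense strand.
    """
    cov = [0] * len(annot.sequence)
    for start, length, count in hits:
        for i in range(max(0, start), min(len(cov), start + length)):
            cov[i] += count
    return HairpinProfile(annot.precursor_id, tuple(cov))


@dataclass(frozen=True)
class HairpinParams:
    min_len: int
    max_len: int
    max_loop_len: int
    min_score_per_nt: float
    min_paired_frac_mature: float


# Provisional preset thresholds; plant hairpins are longer with larger loops.
PRESETS: dict[str, HairpinParams] = {
    "animal": HairpinParams(50, 150, 30, 0.5, 0.6),
    "plant": HairpinParams(60, 300, 150, 0.5, 0.6),
}


def _loop_lengths(fr: FoldResult) -> list[int]:
    """Unpaired span of each terminal (innermost) pair."""
    paired_inside = set(fr.pairs)
    loops = []
    for i, j in fr.pairs:
        if not any(i < a and b < j for a, b in paired_inside if (a, b) != (i, j)):
            loops.append(j - i - 1)
    return loops


def hairpin_filter(
    fr: FoldResult,
    annot: PrecursorAnnotation | None = None,
    params: HairpinParams | str = "animal",
) -> tuple[bool, list[str]]:
    """Plausibility check of a candidate hairpin; returns (pass, reasons).

    Reasons on failure: "length" (outside [min_len, max_len]), "unstable"
    (no pairs, or score per nt below threshold), "loop" (a terminal loop
    longer than max_loop_len), "mature_pairing" (an annotated mature arm
    with too few paired bases).
    """
    if isinstance(params, str):
        params = PRESETS[params]
    reasons: list[str] = []
    n = len(fr.sequence)
    if not params.min_len <= n <= params.max_len:
        reasons.append("length")
    if not fr.pairs or fr.score / n < params.min_score_per_nt:
        reasons.append("unstable")
    else:
        if max(_loop_lengths(fr)) > params.max_loop_len:
            reasons.append("loop")
    if annot is not None and fr.pairs:
        paired = fr.paired_positions()
        for arm, (s, e) in annot.arms().items():
            frac = sum(1 for i in range(s, e) if i in paired) / (e - s)
            if frac < params.min_paired_frac_mature:
                reasons.append("mature_pairing")
                break
    return (not reasons, reasons)
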