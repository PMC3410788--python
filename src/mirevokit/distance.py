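"""Kimura two-parameter (K2P) evolutionary distances on miRNA regions.

For a pairwise alignment with transition proportion P (A<->G, C<->T) and
transversion proportion Q over the compared columns,

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Distances are computed separately for the precursor, each mature arm and
each seed region (mature positions 2-8) of a stitched homolog alignment;
identity and the compared length (coverage) accompany each estimate so
downstream screening can enforce minimum-coverage rules. Columns with a
gap or an ambiguous base in either row are excluded from numerator and
denominator (pairwise complete deletion, the standard K2P convention).
The distance on miRNA regions is conventionally written Kmir; Kmir/Ks < 1
(Ks = synonymous divergence, user-supplied) indicates constraint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .annotate import PrecursorAnnotation
from .maf import HomologSet

__all__ = [
    "SubstitutionCounts",
    "DistanceEstimate",
    "count_substitutions",
    "k2p",
    "region_distances",
    "kmir_ks_ratio",
]

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_BASES = _PURINES | _PYRIMIDINES


@dataclass(frozen=True)
class SubstitutionCounts:
    matches: int
    transitions: int
    transversions: int
    gap_columns: int
    ambiguous_columns: int

    @property
    def compared_columns(self) -> int:
        return self.matches + self.transitions + self.transversions

    @property
    def length(self) -> int:
        return self.compared_columns + self.gap_columns + self.ambiguous_columns


@dataclass(frozen=True)
class DistanceEstimate:
    P: float
    Q: float
    kmir: float | None  # None when saturated or no compared columns
    identity: float
    coverage: int  # compared columns, nt
    region: str
    saturated: bool


def count_substitutions(row_a: str, row_b: str) -> SubstitutionCounts:
    """Classify each column of two equal-length gapped rows."""
    if len(row_a) != len(row_b):
        raise ValueError(f"length mismatch: {len(row_a)} vs {len(row_b)}")
    matches = ts = tv = gaps = amb = 0
    for a, b in zip(row_a.upper(), row_b.upper()):
        if a == "-" or b == "-":
            gaps += 1
        elif a not in _BASES or b not in _BASES:
            amb += 1
        elif a == b:
            matches += 1
        elif {a, b} <= _PURINES or {a, b} <= _PYRIMIDINES:
            ts += 1
        else:
            tv += 1
    return SubstitutionCounts(matches, ts, tv, gaps, amb)


def k2p(P: float, Q: float) -> float | None:
    """K2P distance; ``None`` when the log arguments are non-positive
    (substitution saturation, no finite distance)."""
    if P < 0 or Q < 0:
        raise ValueError("P and Q must be non-negative")
    if P + Q > 1:
        raise ValueError("P + Q must not exceed 1")
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        return None
    return -0.5 * math.log(a * math.sqrt(b))


def estimate_distance(counts: SubstitutionCounts, region: str = "precursor") -> DistanceEstimate:
    n = counts.compared_columns
    if n == 0:
        return DistanceEstimate(0.0, 0.0, None, 0.0, 0, region, False)
    P = counts.transitions / n
    Q = counts.transversions / n
    k = k2p(P, Q)
    return DistanceEstimate(P, Q, k, counts.matches / n, n, region, k is None)


def _ungapped_to_columns(gapped: str) -> list[int]:
    """Column index of each ungapped position of a gapped row."""
    return [col for col, ch in enumerate(gapped) if ch != "-"]


def region_columns(ref_row: str, start: int, end: int) -> tuple[int, int]:
    """Map an ungapped reference interval [start, end) to an inclusive-exclusive
    column range on the alignment (interior reference-gap columns included)."""
    cols = _ungapped_to_columns(ref_row)
    if not 0 <= start < end <= len(cols):
        raise ValueError(f"region [{start},{end}) outside precursor (len {len(cols)})")
    return cols[start], cols[end - 1] + 1


def region_distances(
    homologs: HomologSet,
    annot: PrecursorAnnotation | None = None,
    seed_rule: tuple[int, int] = (1, 8),
    all_pairs: bool = False,
) -> pd.DataFrame:
    """Per-(species pair, region) distance table for one homolog set.

    Regions: the full precursor; each annotated mature arm; the seed of
    each arm, ``seed_rule`` giving the 0-based half-open slice within the
    mature (default positions 2-8, 1-based, the standard 7-nt seed). Arm
    intervals live on the ungapped reference precursor and are projected
    through the gapped reference row. Pairs default to reference x other;
    ``all_pairs`` computes every unordered pair. Absent species are skipped.
    """
    ref = homologs.reference
    ref_row = homologs.rows[ref]
    regions: dict[str, tuple[int, int]] = {}
    ncols = len(ref_row)
    if ncols:
        regions["precursor"] = (0, ncols)
    if annot is not None:
        for arm, (s, e) in annot.arms().items():
            regions[f"mature_{arm}"] = region_columns(ref_row, s, e)
            s0, s1 = seed_rule
            regions[f"seed_{arm}"] = region_columns(ref_row, s + s0, s + s1)
    present = [sp for sp in homologs.species_list() if homologs.coverage[sp] != "absent"]
    if all_pairs:
        pairs = [(a, b) for i, a in enumerate(present) for b in present[i + 1 :]]
    else:
        pairs = [(ref, sp) for sp in present if sp != ref]
    records = []
    for a, b in pairs:
        for region, (c0, c1) in regions.items():
            counts = count_substitutions(homologs.rows[a][c0:c1], homologs.rows[b][c0:c1])
            est = estimate_distance(counts, region)
            records.append(
                {
                    "precursor": homologs.precursor_id,
                    "species_pair": f"{a}|{b}",
                    "species": b if a == ref else f"{a}|{b}",
                    "region": region,
                    "P": est.P,
                    "Q": est.Q,
                    "kmir": est.kmir,
                    "identity": est.identity,
                    "coverage": est.coverage,
                    "saturated": est.saturated,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "precursor", "species_pair", "species", "region",
            "P", "Q", "kmir", "identity", "coverage", "saturated",
        ],
    )


def kmir_ks_ratio(kmir: float, ks: float) -> float:
    """Constraint index: region distance over the neutral synonymous yardstick."""
    if ks <= 0:
        raise ValueError("ks must be positive")
    if kmir < 0:
        raise ValueError("kmir must be non-negative")
    return kmir / ks
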