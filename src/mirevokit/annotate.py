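"""Hierarchical read filtering and known-miRNA expression profiling.

Reads are first filtered against an annotation database (rRNA, scRNA,
snRNA, snoRNA, tRNA, coding regions): anything aligning within the
configured mismatch bound on either strand is discarded from miRNA
analysis. Surviving reads are profiled against known miRNA precursors
(sense strand only, <=1 mismatch, best stratum, all hits) and assigned to
the 5p or 3p mature arm when at least half of the read overlaps that arm's
interval. Reads hitting no precursor are returned as leftover — the input
for external novel-miRNA prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .aligner import Hit, align, build_index
from .smallrna import CollapsedRead, normalize_sequence

__all__ = [
    "FilterConfig",
    "PrecursorAnnotation",
    "ExpressionRecord",
    "filter_by_db",
    "profile_known",
    "read_arms_bed",
    "write_arms_bed",
]


@dataclass(frozen=True)
class FilterConfig:
    """Mismatch policy for the two mapping steps."""

    max_mismatch_db: int = 2  # $MIS: "up to two mismatches" against the db
    max_mismatch_mirna: int = 1  # fixed by the precursor-mapping contract
    sense_only_mirna: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.max_mismatch_db <= 3:
            raise ValueError("max_mismatch_db must be in [0, 3]")


@dataclass(frozen=True)
class PrecursorAnnotation:
    """A precursor hairpin with 0-based half-open mature-arm intervals."""

    precursor_id: str
    sequence: str
    mature_5p: tuple[int, int] | None = None
    mature_3p: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        n = len(self.sequence)
        for arm, iv in (("5p", self.mature_5p), ("3p", self.mature_3p)):
            if iv is None:
                continue
            s, e = iv
            if not (0 <= s < e <= n):
                raise ValueError(f"{self.precursor_id}: {arm} arm {iv} outside precursor [0,{n})")
        if self.mature_5p and self.mature_3p and self.mature_5p[1] > self.mature_3p[0]:
            raise ValueError(f"{self.precursor_id}: 5p arm must precede 3p arm")

    def arms(self) -> dict[str, tuple[int, int]]:
        out = {}
        if self.mature_5p:
            out["5p"] = self.mature_5p
        if self.mature_3p:
            out["3p"] = self.mature_3p
        return out


@dataclass
class ExpressionRecord:
    precursor_id: str
    total_count: int = 0
    count_5p: int = 0
    count_3p: int = 0
    unassigned_count: int = 0

    def validate(self) -> None:
        if self.count_5p + self.count_3p + self.unassigned_count != self.total_count:
            raise AssertionError(f"{self.precursor_id}: arm counts do not sum to total")


def filter_by_db(
    reads: Sequence[CollapsedRead],
    db: Mapping[str, str] | Iterable[tuple[str, str]],
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[CollapsedRead], list[CollapsedRead]]:
    """Partition reads into (discarded, retained) against the annotation db.

    A read is discarded iff it has at least one alignment (either strand)
    within ``cfg.max_mismatch_db`` mismatches. The partition is exhaustive
    and disjoint; database entry order cannot affect it.
    """
    index = build_index(db)
    discarded, retained = [], []
    for read in reads:
        hits = align(read, index, max_mismatch=cfg.max_mismatch_db, sense_only=False)
        (discarded if hits else retained).append(read)
    return discarded, retained


def _arm_for_hit(hit: Hit, read_len: int, annot: PrecursorAnnotation) -> str:
    """Assign a hit to '5p'/'3p' when >=50% of the read overlaps that arm."""
    r0, r1 = hit.start, hit.start + read_len
    for arm, (a0, a1) in annot.arms().items():
        overlap = min(r1, a1) - max(r0, a0)
        if overlap * 2 >= read_len:
            return arm
    return "unassigned"


def profile_known(
    reads: Sequence[CollapsedRead],
    annots: Sequence[PrecursorAnnotation],
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[ExpressionRecord], list[CollapsedRead]]:
    """Expression profile over known precursors + leftover reads.

    Each read contributes its full collapsed count to every best-stratum
    precursor it hits (all-hit reporting; multi-mapped reads are counted
    per locus). Reads with no precursor hit are returned untouched.
    """
    by_id = {a.precursor_id: a for a in annots}
    if len(by_id) != len(annots):
        raise ValueError("duplicate precursor_id in annotations")
    index = build_index({a.precursor_id: a.sequence for a in annots})
    records = {pid: ExpressionRecord(pid) for pid in by_id}
    leftover: list[CollapsedRead] = []
    for read in reads:
        hits = align(
            read,
            index,
            max_mismatch=cfg.max_mismatch_mirna,
            sense_only=cfg.sense_only_mirna,
        )
        if not hits:
            leftover.append(read)
            continue
        for hit in hits:
            rec = records[hit.target_id]
            rec.total_count += read.count
            arm = _arm_for_hit(hit, len(read), by_id[hit.target_id])
            if arm == "5p":
                rec.count_5p += read.count
            elif arm == "3p":
                rec.count_3p += read.count
            else:
                rec.unassigned_count += read.count
    out = [records[pid] for pid in sorted(records)]
    for rec in out:
        rec.validate()
    return out, leftover


# ---------------------------------------------------------------------------
# Arm coordinates as BED6 (chrom = precursor_id, name carries the arm label)
# ---------------------------------------------------------------------------

def read_arms_bed(path: str | Path) -> dict[str, dict[str, tuple[int, int]]]:
    """Parse BED6 arm intervals: {precursor_id: {'5p'|'3p': (start, end)}}."""
    arms: dict[str, dict[str, tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: BED needs >=4 columns")
            pid, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if "5p" in name:
                arm = "5p"
            elif "3p" in name:
                arm = "3p"
            else:
                raise ValueError(f"{path}: line {lineno}: name {name!r} lacks a 5p/3p label")
            arms.setdefault(pid, {})[arm] = (start, end)
    return arms


def write_arms_bed(annots: Sequence[PrecursorAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in annots:
            for arm, (s, e) in a.arms().items():
                fh.write(f"{a.precursor_id}\t{s}\t{e}\t{a.precursor_id}-{arm}\t0\t+\n")


def annotations_from_files(
    precursor_fasta: Sequence[tuple[str, str]],
    arms: Mapping[str, Mapping[str, tuple[int, int]]],
) -> list[PrecursorAnnotation]:
    """Join a precursor FASTA with BED arm intervals."""
    out = []
    for pid, seq in precursor_fasta:
        a = arms.get(pid, {})
        out.append(
            PrecursorAnnotation(pid, seq, a.get("5p"), a.get("3p"))
        )
    return out
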