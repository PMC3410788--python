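"""Small-RNA read I/O, 3'-adapter trimming and read collapsing.

Deep-sequencing small-RNA libraries carry the 3' sequencing adapter on
most reads because inserts (~18-26 nt) are shorter than the read length.
Preprocessing removes the adapter, drops inserts that became too short,
and collapses identical sequences into unique tags with multiplicities
(the "collapsed FASTA" dialect ``>lib_rank_xCOUNT`` used throughout the
small-RNA field).

All sequences are normalized to uppercase DNA (U -> T) internally; report
writers can render RNA again with :func:`to_rna`.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

__all__ = [
    "RawRead",
    "CollapsedRead",
    "TrimStatus",
    "TrimResult",
    "trim_adapter",
    "collapse_reads",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "read_collapsed_fasta",
    "write_collapsed_fasta",
    "normalize_sequence",
    "to_rna",
    "revcomp",
]

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SmallRnaFormatError(ValueError):
    """Malformed sequence record or sequence alphabet violation."""


def normalize_sequence(seq: str) -> str:
    """Uppercase, RNA->DNA (U->T); reject non-nucleotide characters."""
    s = seq.upper().replace("U", "T")
    if not s:
        raise SmallRnaFormatError("empty sequence")
    bad = set(s) - _VALID
    if bad:
        raise SmallRnaFormatError(f"non-nucleotide characters: {sorted(bad)}")
    return s


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RawRead:
    """One sequencing read (qualities are not retained)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CollapsedRead:
    """A unique read sequence with its multiplicity in the library."""

    tag_id: str
    sequence: str
    count: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.count < 1:
            raise ValueError("count must be a positive integer")

    def __len__(self) -> int:
        return len(self.sequence)


class TrimStatus(enum.Enum):
    TRIMMED = "trimmed"
    UNTRIMMED = "untrimmed"
    DISCARDED = "discarded"


@dataclass(frozen=True)
class TrimResult:
    read: RawRead | None  # None when discarded
    status: TrimStatus


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_adapter(
    read: RawRead,
    adapter: str,
    min_overlap: int = 6,
    min_len: int = 18,
    max_mismatch_frac: float = 0.1,
) -> TrimResult:
    """Remove a 3' adapter by leftmost suffix(read)/prefix(adapter) match.

    The candidate adapter start is scanned left to right; the first
    position where the read/adapter overlap (full adapter length for
    internal occurrences, read suffix vs adapter prefix at the 3' end)
    is at least ``min_overlap`` long with a mismatch fraction at most
    ``max_mismatch_frac`` defines the insert. Inserts shorter than
    ``min_len`` are discarded; reads without a match are returned
    unchanged and flagged untrimmed.
    """
    if not adapter:
        raise ValueError("empty adapter")
    adapter = normalize_sequence(adapter)
    if min_overlap < 4:
        raise ValueError("min_overlap must be >= 4")
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    seq = read.sequence
    for i in range(len(seq)):
        overlap = min(len(seq) - i, len(adapter))
        if overlap < min_overlap:
            break
        mm = _mismatches(seq[i : i + overlap], adapter[:overlap])
        if mm / overlap <= max_mismatch_frac:
            insert = seq[:i]
            if len(insert) < min_len:
                return TrimResult(None, TrimStatus.DISCARDED)
            return TrimResult(RawRead(read.id, insert), TrimStatus.TRIMMED)
    return TrimResult(read, TrimStatus.UNTRIMMED)


def collapse_reads(reads: Iterable[RawRead], lib_label: str = "seq") -> list[CollapsedRead]:
    """Collapse identical sequences into unique tags with counts.

    Tags are ``<lib_label>_<rank>_x<count>`` with rank 1..n ordered by
    count descending, ties broken lexicographically by sequence, so the
    output is deterministic regardless of input order.
    """
    counts = Counter(r.sequence for r in reads)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        CollapsedRead(f"{lib_label}_{rank}_x{n}", seq, n)
        for rank, (seq, n) in enumerate(ordered, start=1)
    ]


# ---------------------------------------------------------------------------
# File formats (FASTA, FASTQ, collapsed-FASTA dialect)
# ---------------------------------------------------------------------------

def _check_fasta_head(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise SmallRnaFormatError(
                    f"{path}: line {lineno}: FASTA must start with '>'"
                )
            return
    raise SmallRnaFormatError(f"{path}: empty FASTA file")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as (id, normalized sequence) tuples."""
    _check_fasta_head(path)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise SmallRnaFormatError(f"{path}: record {rec.id!r} has empty sequence")
        out.append((rec.id, normalize_sequence(str(rec.seq))))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, rna: bool = False) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{to_rna(seq) if rna else seq}\n")


def read_fastq(path: str | Path) -> list[RawRead]:
    """Read FASTQ; qualities are parsed (format validation) then dropped."""
    try:
        return [RawRead(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]
    except ValueError as exc:
        raise SmallRnaFormatError(f"{path}: malformed FASTQ ({exc})") from exc


def parse_collapsed_header(header: str) -> tuple[str, int]:
    """Split a ``lib_rank_xCOUNT`` tag into (tag_id, count)."""
    parts = header.rsplit("_x", 1)
    if len(parts) != 2 or not parts[1].isdigit() or int(parts[1]) < 1:
        raise SmallRnaFormatError(
            f"header {header!r} is not in the collapsed dialect 'lib_rank_xCOUNT'"
        )
    return header, int(parts[1])


def read_collapsed_fasta(path: str | Path) -> list[CollapsedRead]:
    out = []
    for rid, seq in read_fasta(path):
        tag, count = parse_collapsed_header(rid)
        out.append(CollapsedRead(tag, seq, count))
    return out


def write_collapsed_fasta(reads: Sequence[CollapsedRead], path: str | Path) -> None:
    write_fasta(((r.tag_id, r.sequence) for r in reads), path)


def preprocess_reads(
    reads: Iterable[RawRead],
    adapter: str,
    lib_label: str = "seq",
    min_overlap: int = 6,
    min_len: int = 18,
    max_mismatch_frac: float = 0.1,
    keep_untrimmed: bool = True,
) -> tuple[list[CollapsedRead], dict[str, int]]:
    """Trim + collapse in one pass; returns collapsed reads and status tally."""
    surviving: list[RawRead] = []
    tally = {s.value: 0 for s in TrimStatus}
    for read in reads:
        res = trim_adapter(read, adapter, min_overlap, min_len, max_mismatch_frac)
        tally[res.status.value] += 1
        if res.status is TrimStatus.TRIMMED:
            surviving.append(res.read)
        elif res.status is TrimStatus.UNTRIMMED and keep_untrimmed:
            surviving.append(res.read)
    return collapse_reads(surviving, lib_label), tally
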