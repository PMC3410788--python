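"""MAF whole-genome alignments: parsing, region slicing, homolog stitching.

The homolog-identification route: place a miRNA precursor on the reference
genome, excise the overlapping columns from a multiz-style MAF (the
reference species is the first row of every block), and stitch the
per-species rows across blocks into one gapped homolog alignment. Synteny
in the WGA is what lets rapidly evolving miRNAs be recovered where a plain
sequence search fails.

Coordinates are 0-based half-open on the forward strand everywhere in this
package; MAF rows keep the native strand-relative (start, size, srcSize)
convention and are converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .smallrna import revcomp

__all__ = [
    "MafRow",
    "MafBlock",
    "GenomeInterval",
    "HomologSet",
    "parse_maf",
    "write_maf",
    "locate_precursor",
    "slice_maf",
    "extract_homologs",
    "screen_orthologs",
]


class MafFormatError(ValueError):
    pass


class LocateError(ValueError):
    """Precursor placement failed (not found, or ambiguous)."""


@dataclass(frozen=True)
class GenomeInterval:
    chrom: str
    start: int  # 0-based half-open, forward strand
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class MafRow:
    """One 's' line: start is 0-based on the row's own strand."""

    src: str  # "assembly.chrom"
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def chrom(self) -> str:
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) == 2 else parts[0]

    def forward_interval(self) -> tuple[int, int]:
        """Half-open forward-strand interval of this row's bases."""
        if self.strand == "+":
            return self.start, self.start + self.size
        return self.src_size - self.start - self.size, self.src_size - self.start

    def ungapped(self) -> str:
        return self.text.replace("-", "")


@dataclass
class MafBlock:
    rows: list[MafRow]
    score: float | None = None

    @property
    def ncols(self) -> int:
        return len(self.rows[0].text) if self.rows else 0

    def validate(self, block_index: int | None = None) -> None:
        where = "" if block_index is None else f" (block {block_index})"
        if not self.rows:
            raise MafFormatError(f"empty block{where}")
        ncols = len(self.rows[0].text)
        for row in self.rows:
            if len(row.text) != ncols:
                raise MafFormatError(
                    f"row {row.src}: text length {len(row.text)} != {ncols}{where}"
                )
            nongap = len(row.ungapped())
            if nongap != row.size:
                raise MafFormatError(
                    f"row {row.src}: {nongap} non-gap chars but size={row.size}{where}"
                )
            if row.start + row.size > row.src_size:
                raise MafFormatError(
                    f"row {row.src}: start+size exceeds srcSize{where}"
                )

    def row_for_species(self, species: str) -> MafRow | None:
        for row in self.rows:
            if row.species == species:
                return row
        return None


def parse_maf(path: str | Path) -> list[MafBlock]:
    """Parse UCSC MAF ('a'/'s' content; 'i'/'e'/'q' lines tolerated and dropped)."""
    blocks: list[MafBlock] = []
    for i, aln in enumerate(AlignIO.parse(str(path), "maf")):
        rows = []
        for rec in aln:
            ann = rec.annotations
            rows.append(
                MafRow(
                    src=rec.id,
                    start=int(ann["start"]),
                    size=int(ann["size"]),
                    strand="+" if ann["strand"] in (1, "+") else "-",
                    src_size=int(ann["srcSize"]),
                    text=str(rec.seq).upper(),
                )
            )
        # Biopython keeps block-level 'a' line fields in ._annotations
        score = {**getattr(aln, "_annotations", {}), **aln.annotations}.get("score")
        block = MafBlock(rows, float(score) if score is not None else None)
        block.validate(block_index=i)
        blocks.append(block)
    return blocks


def write_maf(blocks: Sequence[MafBlock], path: str | Path) -> None:
    """Write blocks as MAF; round-trips 'a'/'s' content through parse_maf."""
    alns = []
    for block in blocks:
        recs = []
        for row in block.rows:
            rec = SeqRecord(Seq(row.text), id=row.src, description="")
            rec.annotations = {
                "start": row.start,
                "size": row.size,
                "strand": 1 if row.strand == "+" else -1,
                "srcSize": row.src_size,
            }
            recs.append(rec)
        aln = MultipleSeqAlignment(recs)
        aln._annotations = {"score": repr(block.score if block.score is not None else 0.0)}
        alns.append(aln)
    with open(path, "w") as fh:
        AlignIO.write(alns, fh, "maf")


# ---------------------------------------------------------------------------
# Precursor placement on the reference genome
# ---------------------------------------------------------------------------

def _exact_placements(pattern: str, genome: Mapping[str, str]) -> list[GenomeInterval]:
    found = []
    for chrom, seq in genome.items():
        for probe, strand in ((pattern, "+"), (revcomp(pattern), "-")):
            pos = seq.find(probe)
            while pos != -1:
                found.append(GenomeInterval(chrom, pos, pos + len(pattern), strand))
                pos = seq.find(probe, pos + 1)
    return found


def _seeded_placements(
    pattern: str, genome: Mapping[str, str], min_identity: float, seed_k: int = 11
) -> list[GenomeInterval]:
    """Ungapped seeded placement: k-mer anchors, full-length identity check."""
    L = len(pattern)
    best: dict[GenomeInterval, float] = {}
    for chrom, seq in genome.items():
        kmers: dict[str, list[int]] = {}
        for off in range(len(seq) - seed_k + 1):
            kmers.setdefault(seq[off : off + seed_k], []).append(off)
        for probe, strand in ((pattern, "+"), (revcomp(pattern), "-")):
            starts = set()
            for s in range(0, L - seed_k + 1, seed_k):
                for off in kmers.get(probe[s : s + seed_k], ()):
                    start = off - s
                    if 0 <= start <= len(seq) - L:
                        starts.add(start)
            for start in starts:
                window = seq[start : start + L]
                ident = sum(a == b for a, b in zip(probe, window)) / L
                if ident >= min_identity:
                    best[GenomeInterval(chrom, start, start + L, strand)] = ident
    if not best:
        return []
    top = max(best.values())
    return [iv for iv, ident in sorted(best.items(), key=lambda kv: (kv[0].chrom, kv[0].start)) if ident == top]


def locate_precursor(
    precursor: str,
    genome: Mapping[str, str],
    min_identity: float = 0.95,
    min_len: int = 40,
) -> GenomeInterval:
    """Unique best placement of a precursor on the reference genome.

    Exact substring search on both strands first; fallback is a seeded
    ungapped scan accepting placements with >= ``min_identity`` over the
    full precursor length. Ambiguity (several equally good loci) raises.
    """
    if len(precursor) < min_len:
        raise ValueError(f"precursor shorter than {min_len} nt")
    hits = _exact_placements(precursor, genome)
    if not hits:
        hits = _seeded_placements(precursor, genome, min_identity)
    if not hits:
        raise LocateError("precursor not found in the reference genome")
    if len(hits) > 1:
        loci = ", ".join(f"{h.chrom}:{h.start}-{h.end}({h.strand})" for h in hits)
        raise LocateError(f"ambiguous placement ({len(hits)} equally good loci): {loci}")
    return hits[0]


# ---------------------------------------------------------------------------
# Region excision (mafsInRegion-equivalent) and homolog stitching
# ---------------------------------------------------------------------------

def _subrow(row: MafRow, c0: int, c1: int) -> MafRow:
    """Row restricted to columns [c0, c1); start/size recomputed."""
    consumed = len(row.text[:c0].replace("-", ""))
    text = row.text[c0:c1]
    return MafRow(
        src=row.src,
        start=row.start + consumed,
        size=len(text.replace("-", "")),
        strand=row.strand,
        src_size=row.src_size,
        text=text,
    )


def slice_maf(blocks: Sequence[MafBlock], query: GenomeInterval) -> list[MafBlock]:
    """Excise the columns of each block overlapping ``query`` on the reference.

    The reference is the first row of each block and must be forward-strand
    (standard multiz layout). The slice spans from the first to the last
    column whose reference character is a non-gap base inside
    [query.start, query.end); interior reference-gap columns (insertions in
    other species) are retained.
    """
    out: list[MafBlock] = []
    for block in blocks:
        ref = block.rows[0]
        if ref.strand != "+":
            raise MafFormatError("reference row must be forward-strand")
        if ref.chrom != query.chrom:
            continue
        if ref.start + ref.size <= query.start or ref.start >= query.end:
            continue
        pos = ref.start
        c0 = c1 = None
        for col, ch in enumerate(ref.text):
            if ch != "-":
                if query.start <= pos < query.end:
                    if c0 is None:
                        c0 = col
                    c1 = col
                pos += 1
        if c0 is None:
            continue
        out.append(MafBlock([_subrow(r, c0, c1 + 1) for r in block.rows], block.score))
    return out


@dataclass
class HomologSet:
    """Stitched per-species gapped homolog rows for one precursor region."""

    precursor_id: str
    reference: str  # reference species name
    rows: dict[str, str]  # species -> gapped row, all same length
    intervals: dict[str, list[tuple[str, int, int, str]]]  # (chrom, fwd start, fwd end, strand)
    coverage: dict[str, str]  # species -> complete | partial | absent
    query: GenomeInterval | None = None

    @property
    def ncols(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ungapped(self, species: str) -> str:
        return self.rows[species].replace("-", "")

    def species_list(self) -> list[str]:
        return list(self.rows)


def extract_homologs(
    sliced: Sequence[MafBlock],
    species: Sequence[str],
    query: GenomeInterval,
    precursor_id: str = "precursor",
) -> HomologSet:
    """Stitch sliced blocks into one per-species gapped alignment.

    Blocks are concatenated in reference order. Species missing from some
    blocks are padded with gap columns there and flagged ``partial``;
    species in no block are flagged ``absent`` (empty row). Overlapping
    blocks on the reference indicate a malformed single-coverage MAF.
    """
    if not sliced:
        return HomologSet(
            precursor_id,
            species[0] if species else "",
            {sp: "" for sp in species},
            {sp: [] for sp in species},
            {sp: "absent" for sp in species},
            query,
        )
    ref_species = sliced[0].rows[0].species
    ordered = sorted(sliced, key=lambda b: b.rows[0].start)
    prev_end = None
    for b in ordered:
        r = b.rows[0]
        if prev_end is not None and r.start < prev_end:
            raise MafFormatError(
                "blocks overlap on the reference; expected single-coverage MAF"
            )
        prev_end = r.start + r.size
    all_species = list(dict.fromkeys([ref_species, *species]))
    rows = {sp: [] for sp in all_species}
    intervals: dict[str, list[tuple[str, int, int, str]]] = {sp: [] for sp in all_species}
    present_in: dict[str, int] = {sp: 0 for sp in all_species}
    for b in ordered:
        ncols = b.ncols
        for sp in all_species:
            row = b.row_for_species(sp)
            if row is None:
                rows[sp].append("-" * ncols)
            else:
                rows[sp].append(row.text)
                present_in[sp] += 1
                if row.size > 0:
                    f0, f1 = row.forward_interval()
                    intervals[sp].append((row.chrom, f0, f1, row.strand))
    coverage = {}
    for sp in all_species:
        if present_in[sp] == 0:
            coverage[sp] = "absent"
        elif present_in[sp] < len(ordered):
            coverage[sp] = "partial"
        else:
            coverage[sp] = "complete"
    return HomologSet(
        precursor_id,
        ref_species,
        {sp: "".join(parts) for sp, parts in rows.items()},
        intervals,
        coverage,
        query,
    )


# ---------------------------------------------------------------------------
# Ortholog screening (identity/coverage/read-support thresholds)
# ---------------------------------------------------------------------------

def screen_orthologs(
    distances: pd.DataFrame,
    expression: pd.DataFrame,
    identity_min: float = 0.90,
    coverage_min: int = 50,
    min_reads: int = 10,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter (precursor, species) ortholog candidates by three criteria:
    sequence identity >= ``identity_min`` over a compared length strictly
    greater than ``coverage_min`` nt, and read support >= ``min_reads``.

    ``distances`` needs columns precursor, species, identity, coverage;
    ``expression`` needs precursor, species, reads. Returns the retained
    rows plus a {'retained': r, 'total': t} tally.
    """
    merged = distances.merge(expression, on=["precursor", "species"], how="left")
    merged["reads"] = merged["reads"].fillna(0)
    keep = (
        (merged["identity"] >= identity_min)
        & (merged["coverage"] > coverage_min)
        & (merged["reads"] >= min_reads)
    )
    retained = merged[keep].reset_index(drop=True)
    return retained, {"retained": int(keep.sum()), "total": int(len(merged))}
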