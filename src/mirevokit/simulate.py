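"""Deterministic synthetic fixtures: toy genomes, mutated orthologous
genomes with known substitution rates, MAF alignments, hairpin
precursors, and Poisson-sampled small-RNA read libraries.

These generators emulate the pipeline's real inputs at desk scale: a
reference genome with planted stem-loop precursors, a second species
derived from it with per-site transition/transversion probabilities (the
ground truth for distance-recovery tests), a multiz-style MAF tiling the
reference, and adapter-carrying read libraries whose per-arm counts are
Poisson draws around configured expression rates. All randomness flows
from one seed; every fixture is reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotate import PrecursorAnnotation
from .maf import MafBlock, MafRow
from .smallrna import RawRead, revcomp

__all__ = [
    "SimulationConfig",
    "PairwiseAlignment",
    "make_genome",
    "make_precursor",
    "plant_precursors",
    "mutate_genome",
    "make_maf",
    "simulate_library",
    "write_fastq",
]

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic test bed.

    Substitution rates default to the canonical recovery setting
    (p*=0.10 transitions, q*=0.05 transversions over 10 kb); indels are
    off by default and, when enabled, avoid planted precursor regions so
    arm projection stays exact.
    """

    seed: int = 1
    genome_length: int = 10_000
    gc_content: float = 0.5
    transition_rate: float = 0.10
    transversion_rate: float = 0.05
    indel_rate: float = 0.0
    indel_in_precursors: bool = False
    n_precursors: int = 6
    stem_len: int = 30
    loop_len: int = 8
    mature_len: int = 22
    library_depth: int = 2_000
    base_arm_rate: float = 0.02
    n_diff: int = 2  # precursors whose 5p arm is differentially expressed
    fold_change: float = 4.0
    read_len: int = 36
    adapter: str = "TCGTATGCCGTCTTCTGCTTG"
    contam_rate: float = 0.05  # fraction of depth drawn from the ncRNA db
    n_db_seqs: int = 4
    species: tuple[str, ...] = ("melsim", "pseudo")

    def __post_init__(self) -> None:
        for name in ("gc_content", "transition_rate", "transversion_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.transition_rate + self.transversion_rate >= 0.5:
            raise ValueError("transition_rate + transversion_rate must be < 0.5")
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if len(self.species) < 2:
            raise ValueError("need at least two species")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def make_genome(cfg: SimulationConfig, rng=None, length: int | None = None) -> str:
    """Random genome at the configured GC content."""
    rng = _rng(cfg.seed if rng is None else rng)
    n = cfg.genome_length if length is None else length
    if n <= 0:
        raise ValueError("genome length must be positive")
    gc = cfg.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(_BASES), size=n, p=probs))


def make_precursor(cfg: SimulationConfig, rng, pid: str) -> PrecursorAnnotation:
    """Perfect stem-loop: 5' arm, loop, reverse-complement 3' arm.

    Mature arms sit one base in from each precursor end (standard Drosha/
    Dicer-style excision geometry at toy scale).
    """
    arm5 = "".join(rng.choice(list(_BASES), size=cfg.stem_len))
    loop = "".join(rng.choice(list(_BASES), size=cfg.loop_len))
    seq = arm5 + loop + revcomp(arm5)
    L = len(seq)
    m = cfg.mature_len
    if cfg.stem_len < m + 2:
        raise ValueError("stem too short for the mature length")
    return PrecursorAnnotation(pid, seq, mature_5p=(1, 1 + m), mature_3p=(L - 1 - m, L - 1))


def plant_precursors(
    genome: str, cfg: SimulationConfig, rng
) -> tuple[str, list[PrecursorAnnotation], dict[str, tuple[int, int]]]:
    """Overwrite evenly spaced genome slices with stem-loop precursors.

    Returns (genome, annotations, {precursor_id: genome interval}).
    """
    pre_len = 2 * cfg.stem_len + cfg.loop_len
    n = cfg.n_precursors
    slot = len(genome) // (n + 1)
    if slot <= pre_len + 10:
        raise ValueError("genome too short for the requested precursors")
    out = list(genome)
    annots, intervals = [], {}
    for i in range(n):
        pid = f"mir-{i + 1}"
        annot = make_precursor(cfg, rng, pid)
        start = (i + 1) * slot
        out[start : start + pre_len] = annot.sequence
        annots.append(annot)
        intervals[pid] = (start, start + pre_len)
    return "".join(out), annots, intervals


@dataclass
class PairwiseAlignment:
    """Column-wise truth of one mutated genome against the reference.

    ``ref_chars[i]`` is the species character aligned to reference
    position i ('-' when deleted); ``insertions[i]`` holds species bases
    inserted immediately after reference position i (i = -1 for a leading
    insertion).
    """

    ref_seq: str
    chars: list[str]
    insertions: dict[int, str] = field(default_factory=dict)

    def alt_seq(self) -> str:
        parts = [self.insertions.get(-1, "")]
        for i, ch in enumerate(self.chars):
            if ch != "-":
                parts.append(ch)
            parts.append(self.insertions.get(i, ""))
        return "".join(parts)

    def gapped_rows(self) -> tuple[str, str]:
        lead = self.insertions.get(-1, "")
        ref_row, alt_row = ["-" * len(lead)], [lead]
        for i, ch in enumerate(self.chars):
            ref_row.append(self.ref_seq[i])
            alt_row.append(ch)
            ins = self.insertions.get(i, "")
            if ins:
                ref_row.append("-" * len(ins))
                alt_row.append(ins)
        return "".join(ref_row), "".join(alt_row)

    def project_interval(self, start: int, end: int) -> tuple[int, int]:
        """Reference [start, end) -> species ungapped coordinates."""
        before = len(self.insertions.get(-1, "")) + sum(
            (1 if self.chars[i] != "-" else 0) + len(self.insertions.get(i, ""))
            for i in range(start)
        )
        inside = sum(
            (1 if self.chars[i] != "-" else 0) + len(self.insertions.get(i, ""))
            for i in range(start, end)
        ) - len(self.insertions.get(end - 1, ""))
        return before, before + max(0, inside)


def mutate_genome(
    genome: str,
    cfg: SimulationConfig,
    rng,
    protected: Sequence[tuple[int, int]] = (),
) -> PairwiseAlignment:
    """Mutate per site: transition with p*, transversion with q*, indels
    (length 1-3) at ``indel_rate``. Protected intervals receive
    substitutions but no indels unless ``indel_in_precursors`` is set."""
    rng = _rng(rng)
    prot = np.zeros(len(genome), dtype=bool)
    if not cfg.indel_in_precursors:
        for s, e in protected:
            prot[s:e] = True
    chars: list[str] = []
    insertions: dict[int, str] = {}
    u_sub = rng.random(len(genome))
    i = 0
    while i < len(genome):
        base = genome[i]
        if cfg.indel_rate > 0 and not prot[i] and rng.random() < cfg.indel_rate:
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion of up to `length` unprotected sites
                for j in range(i, min(i + length, len(genome))):
                    if prot[j]:
                        break
                    chars.append("-")
                    i += 1
                continue
            insertions[i - 1] = "".join(rng.choice(list(_BASES), size=length))
        u = u_sub[i]
        if u < cfg.transition_rate:
            chars.append(_TRANSITION[base])
        elif u < cfg.transition_rate + cfg.transversion_rate:
            chars.append(_TRANSVERSIONS[base][int(rng.integers(0, 2))])
        else:
            chars.append(base)
        i += 1
    return PairwiseAlignment(genome, chars, insertions)


def make_maf(
    reference: tuple[str, str],
    species_variants: Sequence[tuple[str, PairwiseAlignment]],
    block_cols: int = 500,
    chrom: str = "chr1",
) -> list[MafBlock]:
    """Merge per-species pairwise truths into reference-threaded MAF blocks.

    Insertions of different species are emitted as separate columns (they
    are unaligned to each other); blocks tile the reference with at most
    ``block_cols`` columns each. The reference row comes first, as in
    multiz output.
    """
    ref_name, ref_seq = reference
    names = [ref_name] + [name for name, _ in species_variants]
    columns: list[tuple[str, ...]] = []
    for si, (name, aln) in enumerate(species_variants):
        ins = aln.insertions.get(-1, "")
        for ch in ins:
            col = ["-"] * (len(species_variants) + 1)
            col[si + 1] = ch
            columns.append(tuple(col))
    for i, base in enumerate(ref_seq):
        col = [base] + [aln.chars[i] for _, aln in species_variants]
        columns.append(tuple(col))
        for si, (name, aln) in enumerate(species_variants):
            for ch in aln.insertions.get(i, ""):
                icol = ["-"] * (len(species_variants) + 1)
                icol[si + 1] = ch
                columns.append(tuple(icol))
    seq_lens = [len(ref_seq)] + [len(aln.alt_seq()) for _, aln in species_variants]
    starts = [0] * len(names)
    blocks: list[MafBlock] = []
    for b0 in range(0, len(columns), block_cols):
        chunk = columns[b0 : b0 + block_cols]
        rows = []
        for r, name in enumerate(names):
            text = "".join(col[r] for col in chunk)
            size = len(text) - text.count("-")
            rows.append(
                MafRow(
                    src=f"{name}.{chrom}",
                    start=starts[r],
                    size=size,
                    strand="+",
                    src_size=seq_lens[r],
                    text=text,
                )
            )
            starts[r] += size
        block = MafBlock(rows, score=0.0)
        block.validate()
        blocks.append(block)
    return blocks


def simulate_library(
    annots: Sequence[PrecursorAnnotation],
    rates: Mapping[tuple[str, str], float],
    depth: int,
    rng,
    adapter: str = "TCGTATGCCGTCTTCTGCTTG",
    read_len: int = 36,
    wobble: int = 2,
    lib_label: str = "lib",
    db: Mapping[str, str] | None = None,
    contam_rate: float = 0.0,
) -> list[RawRead]:
    """Poisson-sampled adapter-carrying reads from mature arms.

    Per arm, the read count is Poisson(rate * depth); each read is the
    mature substring with 0-``wobble`` nt end wobble, 3' adapter appended
    and the whole truncated to ``read_len``. Optional contaminant reads
    are random substrings of db sequences (rRNA/tRNA stand-ins) at
    Poisson(contam_rate * depth) per db entry.
    """
    rng = _rng(rng)
    reads: list[RawRead] = []
    serial = 0
    for annot in annots:
        for arm, (s, e) in sorted(annot.arms().items()):
            rate = rates.get((annot.precursor_id, arm), 0.0)
            count = int(rng.poisson(rate * depth)) if rate > 0 else 0
            for _ in range(count):
                s2 = max(0, s + int(rng.integers(-wobble, wobble + 1)))
                e2 = min(len(annot.sequence), e + int(rng.integers(-wobble, wobble + 1)))
                insert = annot.sequence[s2:e2]
                serial += 1
                reads.append(
                    RawRead(f"{lib_label}_r{serial:06d}", (insert + adapter)[:read_len])
                )
    if db and contam_rate > 0:
        for name in sorted(db):
            seq = db[name]
            count = int(rng.poisson(contam_rate * depth))
            for _ in range(count):
                if len(seq) <= 22:
                    insert = seq
                else:
                    s0 = int(rng.integers(0, len(seq) - 22 + 1))
                    insert = seq[s0 : s0 + 22]
                serial += 1
                reads.append(
                    RawRead(f"{lib_label}_r{serial:06d}", (insert + adapter)[:read_len])
                )
    return reads


def default_rates(
    annots: Sequence[PrecursorAnnotation], cfg: SimulationConfig, species_index: int
) -> dict[tuple[str, str], float]:
    """Per-arm expression rates; the first ``n_diff`` precursors' 5p arms
    carry a ``fold_change`` up-shift in every non-reference species."""
    rates: dict[tuple[str, str], float] = {}
    for i, annot in enumerate(annots):
        for arm in annot.arms():
            rate = cfg.base_arm_rate
            if arm == "5p" and i < cfg.n_diff and species_index > 0:
                rate *= cfg.fold_change
            rates[(annot.precursor_id, arm)] = rate
    return rates


def make_db(cfg: SimulationConfig, rng) -> dict[str, str]:
    """Random ncRNA-like decoy sequences (tRNA/rRNA stand-ins)."""
    rng = _rng(rng)
    return {
        f"ncRNA-{i + 1}": "".join(rng.choice(list(_BASES), size=120))
        for i in range(cfg.n_db_seqs)
    }


def write_fastq(reads: Sequence[RawRead], path: str | Path, quality: str = "I") -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{quality * len(r.sequence)}\n")
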