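"""Crosscheck predicted novel miRNAs against a known-miRNA catalogue.

A candidate is reported against a known mature miRNA when the 7-nt seeds
(mature positions 2-8) are identical, or when global mature-sequence
identity exceeds a threshold (default 80%), or both; the rule that fired
is recorded so stricter filtering can be applied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from .smallrna import normalize_sequence, to_rna

__all__ = ["MatureRecord", "CrosscheckHit", "seed_of", "mature_identity", "crosscheck"]


@dataclass(frozen=True)
class MatureRecord:
    """A mature miRNA (miRBase-style id, e.g. 'dme-miR-310')."""

    id: str
    sequence: str  # stored as RNA
    species: str = ""

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sequence)
        if len(seq) < 18:
            raise ValueError(f"{self.id}: mature sequence shorter than 18 nt")
        object.__setattr__(self, "sequence", to_rna(seq))
        if not self.species and "-" in self.id:
            object.__setattr__(self, "species", self.id.split("-", 1)[0])

    @property
    def seed(self) -> str:
        return seed_of(self.sequence)


@dataclass(frozen=True)
class CrosscheckHit:
    candidate_id: str
    known_id: str
    seed_identical: bool
    mature_identity: float
    rule_fired: str  # 'seed' | 'identity' | 'both'


def seed_of(mature: str) -> str:
    """Seed = 1-based positions 2-8 (7 nt) of the mature, RNA alphabet."""
    seq = normalize_sequence(mature)
    if len(seq) < 8:
        raise ValueError("mature sequence shorter than 8 nt has no seed")
    return to_rna(seq[1:8])


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def mature_identity(a: str, b: str) -> float:
    """Identity of the best global alignment, over alignment columns
    (match 1 / mismatch 0 / gap -1 scoring for the alignment itself)."""
    sa, sb = normalize_sequence(a), normalize_sequence(b)
    aln = _ALIGNER.align(sa, sb)[0]
    cols = aln.length
    matches = sum(
        x == y and x != "-" for x, y in zip(str(aln[0]), str(aln[1]))
    )
    return matches / cols


def crosscheck(
    candidates: Sequence[MatureRecord],
    known: Sequence[MatureRecord],
    identity_min: float = 0.8,
) -> list[CrosscheckHit]:
    """All (candidate, known) pairs passing the seed-or-identity rule.

    Reported iff the seeds are identical OR mature identity is strictly
    greater than ``identity_min`` (inclusive OR; ``rule_fired`` records
    which conditions held).
    """
    if not candidates or not known:
        raise ValueError("candidate and known catalogues must be non-empty")
    hits: list[CrosscheckHit] = []
    for cand in candidates:
        for ref in known:
            seed_same = cand.seed == ref.seed
            ident = mature_identity(cand.sequence, ref.sequence)
            ident_hit = ident > identity_min
            if not (seed_same or ident_hit):
                continue
            rule = "both" if (seed_same and ident_hit) else ("seed" if seed_same else "identity")
            hits.append(CrosscheckHit(cand.id, ref.id, seed_same, ident, rule))
    return hits
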