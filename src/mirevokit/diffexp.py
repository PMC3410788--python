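"""Cross-species expression comparison of orthologous miRNAs.

Each species' reads are mapped (sense-only, <=1 mismatch, best stratum)
to that species' own homolog sequences extracted from the whole-genome
alignment; mature-arm counts follow the arm intervals projected through
the alignment. Counts are normalized to tags per million mapped reads
(TPM = x/N * 1e6).

Differential expression between two libraries uses the Poisson
likelihood-ratio test in closed form. With x_i ~ Poisson(lambda_i * N_i),
the null of a common rate gives expected counts
e_i = N_i * (x1 + x2) / (N1 + N2) and the deviance

    G = 2 * sum_i x_i * ln(x_i / e_i)        (0 * ln 0 = 0)

which is chi-square with 1 df under the null — identical to the LRT of a
two-group Poisson GLM with a log offset, without iterative fitting.
Multiple testing across arms is controlled by Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .aligner import align, build_index
from .annotate import PrecursorAnnotation, _arm_for_hit
from .maf import HomologSet
from .smallrna import CollapsedRead

__all__ = [
    "ArmExpression",
    "LrtResult",
    "tpm",
    "poisson_lrt",
    "yates_chisq",
    "count_orthologs",
    "diff_table",
]


@dataclass(frozen=True)
class ArmExpression:
    precursor_id: str
    species: str
    arm: str  # '5p' | '3p'
    x: int  # summed collapsed counts on this arm
    N: int  # library normalization total (reads mapped to the homolog set)

    @property
    def tpm(self) -> float:
        return tpm(self.x, self.N)


class LrtResult(NamedTuple):
    G: float
    p: float
    degenerate: bool = False  # x1 + x2 == 0: test undefined, p = 1


def tpm(x: int, N: int) -> float:
    """Tags per million mapped reads."""
    if N <= 0:
        raise ValueError("normalization total N must be positive")
    if not 0 <= x <= N:
        raise ValueError("count x must satisfy 0 <= x <= N")
    return x / N * 1e6


def poisson_lrt(x1: int, N1: int, x2: int, N2: int) -> LrtResult:
    """Closed-form two-sample Poisson LRT (G, chi-square 1-df p-value)."""
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    if x1 < 0 or x2 < 0:
        raise ValueError("counts must be non-negative")
    total = x1 + x2
    if total == 0:
        return LrtResult(0.0, 1.0, degenerate=True)
    G = 0.0
    for x, N in ((x1, N1), (x2, N2)):
        e = N * total / (N1 + N2)
        if x > 0:
            G += x * math.log(x / e)
    G = max(0.0, 2.0 * G)
    return LrtResult(G, float(stats.chi2.sf(G, df=1)))


def yates_chisq(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square with Yates continuity correction on a 2x2 table."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    res = stats.chi2_contingency(arr, correction=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Counting reads on species-specific homolog references
# ---------------------------------------------------------------------------

def project_arm(homologs: HomologSet, species: str, start: int, end: int) -> tuple[int, int]:
    """Project an ungapped-reference interval into a species' ungapped
    homolog coordinates through the column alignment."""
    ref_row = homologs.rows[homologs.reference]
    sp_row = homologs.rows[species]
    cols = [c for c, ch in enumerate(ref_row) if ch != "-"]
    if not 0 <= start < end <= len(cols):
        raise ValueError(f"arm [{start},{end}) outside reference homolog")
    c0, c1 = cols[start], cols[end - 1] + 1
    s = len(sp_row[:c0].replace("-", ""))
    e = len(sp_row[:c1].replace("-", ""))
    return s, e


def count_orthologs(
    libraries: Mapping[str, Sequence[CollapsedRead]],
    homolog_sets: Sequence[HomologSet],
    annots: Mapping[str, PrecursorAnnotation],
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """Per-(precursor, species, arm) expression over homolog references.

    For each species, its reads are aligned sense-only within
    ``max_mismatch`` to the ungapped homolog sequences of that species;
    a read's full collapsed count goes to every best-stratum homolog it
    hits, assigned to an arm when >=50% of the read overlaps the
    projected arm interval. N is the total collapsed count mapped to the
    species' homolog reference set. Species with an absent homolog for a
    precursor are skipped for that precursor.
    """
    records = []
    for species, reads in libraries.items():
        if not reads:
            raise ValueError(f"empty library for species {species!r}")
        refs: dict[str, str] = {}
        proj_annots: dict[str, PrecursorAnnotation] = {}
        for hs in homolog_sets:
            if species not in hs.rows or hs.coverage.get(species) == "absent":
                continue
            seq = hs.ungapped(species)
            if not seq:
                continue
            annot = annots[hs.precursor_id]
            arms = {}
            for arm_name, (s, e) in annot.arms().items():
                ps, pe = project_arm(hs, species, s, e)
                if pe > ps:
                    arms[arm_name] = (ps, pe)
            refs[hs.precursor_id] = seq
            proj_annots[hs.precursor_id] = PrecursorAnnotation(
                hs.precursor_id, seq, arms.get("5p"), arms.get("3p")
            )
        if not refs:
            continue
        index = build_index(refs)
        counts: dict[tuple[str, str], int] = {}
        N = 0
        for read in reads:
            hits = align(read, index, max_mismatch=max_mismatch, sense_only=True)
            if not hits:
                continue
            N += read.count
            for hit in hits:
                arm = _arm_for_hit(hit, len(read), proj_annots[hit.target_id])
                key = (hit.target_id, arm)
                counts[key] = counts.get(key, 0) + read.count
        for pid in sorted(refs):
            for arm_name in ("5p", "3p"):
                if arm_name in proj_annots[pid].arms():
                    records.append(
                        {
                            "precursor": pid,
                            "species": species,
                            "arm": arm_name,
                            "x": counts.get((pid, arm_name), 0),
                            "N": N,
                        }
                    )
    df = pd.DataFrame.from_records(records, columns=["precursor", "species", "arm", "x", "N"])
    if not df.empty:
        df["tpm"] = df["x"] / df["N"].where(df["N"] > 0) * 1e6
        df["tpm"] = df["tpm"].fillna(0.0)
    else:
        df["tpm"] = pd.Series(dtype=float)
    return df


def diff_table(
    expr: pd.DataFrame,
    species1: str,
    species2: str,
    alpha: float = 0.05,
    correction: str = "bh",
    pseudocount: int = 1,
) -> pd.DataFrame:
    """Pairwise differential-expression table for two species.

    Arms are matched by (precursor, arm) across the two species and
    tested with the Poisson LRT; q-values are Benjamini-Hochberg over all
    tested arms (``correction='none'`` flags on raw p instead). Scatter
    columns ``log2_tpm_1/2`` use a one-read pseudocount so zeros remain
    plottable; the test itself uses raw counts.
    """
    species = set(expr["species"])
    if species1 not in species or species2 not in species:
        raise ValueError("need expression records for both species")
    a = expr[expr["species"] == species1].set_index(["precursor", "arm"])
    b = expr[expr["species"] == species2].set_index(["precursor", "arm"])
    shared = sorted(set(a.index) & set(b.index))
    if not shared:
        raise ValueError("no (precursor, arm) shared between the two species")
    rows = []
    for key in shared:
        x1, N1 = int(a.loc[key, "x"]), int(a.loc[key, "N"])
        x2, N2 = int(b.loc[key, "x"]), int(b.loc[key, "N"])
        res = poisson_lrt(x1, N1, x2, N2) if x1 + x2 > 0 else LrtResult(0.0, 1.0, True)
        rows.append(
            {
                "precursor": key[0],
                "arm": key[1],
                "x1": x1, "N1": N1, "x2": x2, "N2": N2,
                "G": res.G, "p": res.p, "degenerate": res.degenerate,
                "log2_tpm_1": math.log2((x1 + pseudocount) / N1 * 1e6),
                "log2_tpm_2": math.log2((x2 + pseudocount) / N2 * 1e6),
            }
        )
    df = pd.DataFrame(rows)
    if correction == "bh":
        _, q, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
        df["q"] = q
        df["significant"] = df["q"] < alpha
    elif correction == "none":
        df["q"] = df["p"]
        df["significant"] = df["p"] < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return df


def scatter_table(diff: pd.DataFrame) -> pd.DataFrame:
    """Scatter-ready projection of a diff table (log2 TPM vs log2 TPM)."""
    return diff[["precursor", "arm", "log2_tpm_1", "log2_tpm_2", "significant"]].copy()
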