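"""Stage orchestration: simulate -> preprocess -> filter -> profile ->
homolog -> distance -> diffexp, with a reproducibility manifest.

Every stage reads and writes plain files under the run's output
directory, so any stage can be re-run standalone. The manifest records
the configuration and a SHA-256 checksum of every output; identical
config + seed reproduce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import simulate as sim
from .annotate import (
    FilterConfig,
    annotations_from_files,
    profile_known,
    read_arms_bed,
    write_arms_bed,
    filter_by_db,
)
from .config import RunConfig
from .diffexp import count_orthologs, diff_table, scatter_table
from .distance import region_distances
from .maf import GenomeInterval, extract_homologs, locate_precursor, parse_maf, slice_maf, write_maf
from .smallrna import (
    preprocess_reads,
    read_collapsed_fasta,
    read_fasta,
    read_fastq,
    write_collapsed_fasta,
    write_fasta,
)

logger = logging.getLogger("mirevokit.pipeline")

STAGES = ["simulate", "preprocess", "filter", "profile", "homolog", "distance", "diffexp"]

_REQUIRES = {
    "preprocess": ["simulate/lib_{sp}.fastq"],
    "filter": ["preprocess/collapsed_{sp}.fa", "simulate/db.fa"],
    "profile": ["filter/retained_{sp}.fa", "simulate/precursors.fa", "simulate/arms.bed"],
    "homolog": ["simulate/genome.fa", "simulate/aln.maf", "simulate/precursors.fa"],
    "distance": ["homolog/intervals.tsv", "simulate/arms.bed"],
    "diffexp": ["homolog/intervals.tsv", "filter/retained_{sp}.fa", "simulate/arms.bed"],
}


class StageError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _check_requires(stage: str, out: Path, species: Sequence[str]) -> None:
    for tmpl in _REQUIRES.get(stage, []):
        paths = (
            [tmpl.format(sp=sp) for sp in species] if "{sp}" in tmpl else [tmpl]
        )
        for rel in paths:
            if not (out / rel).exists():
                upstream = rel.split("/", 1)[0]
                raise StageError(
                    f"stage '{stage}' needs {rel}; run stage '{upstream}' first"
                )


def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    s = cfg["simulate"]
    scfg = sim.SimulationConfig(seed=cfg.seed, **{k: tuple(v) if k == "species" else v for k, v in s.items()})
    d = out / "simulate"
    d.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, 11])
    genome = sim.make_genome(scfg, rng)
    genome, annots, intervals = sim.plant_precursors(genome, scfg, rng)
    write_fasta([("chr1", genome)], d / "genome.fa")
    write_fasta([(a.precursor_id, a.sequence) for a in annots], d / "precursors.fa")
    write_arms_bed(annots, d / "arms.bed")
    db = sim.make_db(scfg, np.random.default_rng([cfg.seed, 13]))
    write_fasta(sorted(db.items()), d / "db.fa")

    species = list(scfg.species)
    ref_sp = species[0]
    variants = []
    prot = list(intervals.values())
    for si, sp in enumerate(species[1:], start=1):
        aln = sim.mutate_genome(genome, scfg, np.random.default_rng([cfg.seed, 17, si]), protected=prot)
        variants.append((sp, aln))
        write_fasta([("chr1", aln.alt_seq())], d / f"genome_{sp}.fa")
    blocks = sim.make_maf((ref_sp, genome), variants)
    write_maf(blocks, d / "aln.maf")

    # one read library per species, sampled from that species' own precursors
    for si, sp in enumerate(species):
        if si == 0:
            sp_annots = annots
        else:
            aln = variants[si - 1][1]
            sp_annots = []
            for a in annots:
                g0, g1 = intervals[a.precursor_id]
                p0, p1 = aln.project_interval(g0, g1)
                seq = aln.alt_seq()[p0:p1]
                if len(seq) != len(a.sequence):  # indels hit the precursor
                    continue
                sp_annots.append(
                    type(a)(a.precursor_id, seq, a.mature_5p, a.mature_3p)
                )
        rates = sim.default_rates(sp_annots, scfg, si)
        reads = sim.simulate_library(
            sp_annots,
            rates,
            scfg.library_depth,
            np.random.default_rng([cfg.seed, 19, si]),
            adapter=scfg.adapter,
            read_len=scfg.read_len,
            lib_label=sp,
            db=db,
            contam_rate=scfg.contam_rate,
        )
        sim.write_fastq(reads, d / f"lib_{sp}.fastq")


def _species(cfg: RunConfig) -> list[str]:
    return list(cfg["simulate"]["species"])


def _stage_preprocess(cfg: RunConfig, out: Path) -> None:
    p = cfg["preprocess"]
    adapter = cfg["simulate"]["adapter"]
    d = out / "preprocess"
    d.mkdir(parents=True, exist_ok=True)
    tallies = {}
    for sp in _species(cfg):
        reads = read_fastq(out / "simulate" / f"lib_{sp}.fastq")
        collapsed, tally = preprocess_reads(
            reads,
            adapter,
            lib_label=sp,
            min_overlap=p["min_overlap"],
            min_len=p["min_len"],
            max_mismatch_frac=p["max_mismatch_frac"],
            keep_untrimmed=p["keep_untrimmed"],
        )
        write_collapsed_fasta(collapsed, d / f"collapsed_{sp}.fa")
        tallies[sp] = tally
    (d / "tally.json").write_text(json.dumps(tallies, sort_keys=True, indent=1))


def _stage_filter(cfg: RunConfig, out: Path) -> None:
    fcfg = FilterConfig(max_mismatch_db=cfg["filter"]["max_mismatch_db"])
    db = dict(read_fasta(out / "simulate" / "db.fa"))
    d = out / "filter"
    d.mkdir(parents=True, exist_ok=True)
    for sp in _species(cfg):
        reads = read_collapsed_fasta(out / "preprocess" / f"collapsed_{sp}.fa")
        discarded, retained = filter_by_db(reads, db, fcfg)
        write_collapsed_fasta(retained, d / f"retained_{sp}.fa")
        write_collapsed_fasta(discarded, d / f"discarded_{sp}.fa")


def _load_annotations(out: Path):
    pre = read_fasta(out / "simulate" / "precursors.fa")
    arms = read_arms_bed(out / "simulate" / "arms.bed")
    return annotations_from_files(pre, arms)


def _stage_profile(cfg: RunConfig, out: Path) -> None:
    annots = _load_annotations(out)
    fcfg = FilterConfig(max_mismatch_mirna=cfg["profile"]["max_mismatch_mirna"])
    d = out / "profile"
    d.mkdir(parents=True, exist_ok=True)
    ref_sp = _species(cfg)[0]
    reads = read_collapsed_fasta(out / "filter" / f"retained_{ref_sp}.fa")
    records, leftover = profile_known(reads, annots, fcfg)
    pd.DataFrame(
        [
            {
                "precursor": r.precursor_id,
                "total": r.total_count,
                "count_5p": r.count_5p,
                "count_3p": r.count_3p,
                "unassigned": r.unassigned_count,
            }
            for r in records
        ]
    ).to_csv(d / "expr.tsv", sep="\t", index=False)
    write_collapsed_fasta(leftover, d / "leftover.fa")


def _stage_homolog(cfg: RunConfig, out: Path) -> None:
    genome = dict(read_fasta(out / "simulate" / "genome.fa"))
    blocks = parse_maf(out / "simulate" / "aln.maf")
    pre = read_fasta(out / "simulate" / "precursors.fa")
    species = _species(cfg)
    d = out / "homolog"
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid, seq in pre:
        iv = locate_precursor(seq, genome, min_identity=cfg["homolog"]["min_identity"])
        sliced = slice_maf(blocks, iv)
        write_maf(sliced, d / f"{pid}.maf")
        hs = extract_homologs(sliced, species, iv, precursor_id=pid)
        write_fasta(
            [(sp, hs.ungapped(sp)) for sp in hs.species_list() if hs.coverage[sp] != "absent"],
            d / f"{pid}_homologs.fa",
        )
        for sp in hs.species_list():
            rows.append(
                {
                    "precursor": pid,
                    "species": sp,
                    "coverage_flag": hs.coverage[sp],
                    "chrom": iv.chrom,
                    "ref_start": iv.start,
                    "ref_end": iv.end,
                    "strand": iv.strand,
                }
            )
    pd.DataFrame(rows).to_csv(d / "intervals.tsv", sep="\t", index=False)


def _homolog_sets(cfg: RunConfig, out: Path):
    genome = dict(read_fasta(out / "simulate" / "genome.fa"))
    pre = read_fasta(out / "simulate" / "precursors.fa")
    species = _species(cfg)
    sets = []
    for pid, seq in pre:
        sliced = parse_maf(out / "homolog" / f"{pid}.maf")
        iv = locate_precursor(seq, genome, min_identity=cfg["homolog"]["min_identity"])
        sets.append(extract_homologs(sliced, species, iv, precursor_id=pid))
    return sets


def _stage_distance(cfg: RunConfig, out: Path) -> None:
    annots = {a.precursor_id: a for a in _load_annotations(out)}
    d = out / "distance"
    d.mkdir(parents=True, exist_ok=True)
    tables = [
        region_distances(hs, annots[hs.precursor_id], all_pairs=cfg["distance"]["all_pairs"])
        for hs in _homolog_sets(cfg, out)
    ]
    pd.concat(tables, ignore_index=True).to_csv(
        d / "dist.tsv", sep="\t", index=False, float_format="%.6g"
    )


def _stage_diffexp(cfg: RunConfig, out: Path) -> None:
    annots = {a.precursor_id: a for a in _load_annotations(out)}
    species = _species(cfg)
    libraries = {
        sp: read_collapsed_fasta(out / "filter" / f"retained_{sp}.fa") for sp in species
    }
    d = out / "diffexp"
    d.mkdir(parents=True, exist_ok=True)
    expr = count_orthologs(libraries, _homolog_sets(cfg, out), annots)
    expr.to_csv(d / "expr_by_species.tsv", sep="\t", index=False, float_format="%.6g")
    diff = diff_table(
        expr,
        species[0],
        species[1],
        alpha=cfg["diffexp"]["alpha"],
        correction=cfg["diffexp"]["correction"],
    )
    diff.to_csv(d / "diffexp.tsv", sep="\t", index=False, float_format="%.6g")
    scatter_table(diff).to_csv(d / "scatter.tsv", sep="\t", index=False, float_format="%.6g")


_RUNNERS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "filter": _stage_filter,
    "profile": _stage_profile,
    "homolog": _stage_homolog,
    "distance": _stage_distance,
    "diffexp": _stage_diffexp,
}


def run_pipeline(cfg: RunConfig, stages: Sequence[str] | None = None) -> dict:
    """Execute stages in dependency order and write manifest.json.

    Returns the manifest dict. Re-running with the same config and seed
    reproduces identical output checksums.
    """
    requested = STAGES if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise StageError(f"unknown stages: {sorted(unknown)}")
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    species = _species(cfg)
    manifest: dict = {
        "config": cfg.sections,
        "seed": cfg.seed,
        "stages": {},
    }
    for stage in requested:
        _check_requires(stage, out, species)
        logger.info("running stage %s", stage)
        _RUNNERS[stage](cfg, out)
        stage_dir = out / stage
        outputs = {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(stage_dir.rglob("*"))
            if p.is_file()
        }
        manifest["stages"][stage] = {"outputs": outputs}
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
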