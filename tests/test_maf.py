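"""MAF parsing, region slicing, homolog stitching, ortholog screening."""

import pandas as pd
import pytest

from mirevokit.maf import (
    GenomeInterval,
    LocateError,
    MafBlock,
    MafFormatError,
    MafRow,
    extract_homologs,
    locate_precursor,
    parse_maf,
    screen_orthologs,
    slice_maf,
    write_maf,
)
from mirevokit.simulate import SimulationConfig, make_genome, make_maf, mutate_genome
from mirevokit.smallrna import revcomp

from oracles import reference_chars_in_region

TOY_MAF = """##maf version=1
a score=10.0
s ref.chr1 10 12 + 100 ACGTAC--GTACGT
s spB.chr2  5 14 + 80  ACGTACTTGTACGT
i spB.chr2 N 0 C 0

a score=4.0
s ref.chr1 22 6 + 100 AAATTT
s spC.chr3  0 6 - 50  AAATTT
"""


@pytest.fixture
def toy_blocks(tmp_path):
    path = tmp_path / "toy.maf"
    path.write_text(TOY_MAF)
    return parse_maf(path)


class TestParseWrite:
    def test_parse_toy(self, toy_blocks):
        assert len(toy_blocks) == 2
        assert [r.src for r in toy_blocks[0].rows] == ["ref.chr1", "spB.chr2"]
        assert toy_blocks[0].rows[0].size == 12

    def test_size_mismatch_raises_with_block_index(self, tmp_path):
        bad = "a score=1\ns ref.chr1 0 5 + 100 ACGT\n"
        path = tmp_path / "bad.maf"
        path.write_text(bad)
        with pytest.raises(MafFormatError, match="block 0"):
            parse_maf(path)

    def test_minus_strand_forward_interval(self, toy_blocks):
        row = toy_blocks[1].rows[1]  # spC, minus strand, start 0, size 6, srcSize 50
        assert row.forward_interval() == (44, 50)

    def test_round_trip(self, toy_blocks, tmp_path):
        out = tmp_path / "rt.maf"
        write_maf(toy_blocks, out)
        again = parse_maf(out)
        assert again == toy_blocks


class TestLocate:
    def test_planted_forward(self, small_genome, toy_annot):
        genome = {"chr1": small_genome[:100] + toy_annot.sequence + small_genome[100:]}
        iv = locate_precursor(toy_annot.sequence, genome)
        assert (iv.chrom, iv.start, iv.end, iv.strand) == ("chr1", 100, 170, "+")

    def test_planted_reverse_complement(self, small_genome, toy_annot):
        genome = {"chr1": small_genome[:100] + revcomp(toy_annot.sequence) + small_genome[100:]}
        iv = locate_precursor(toy_annot.sequence, genome)
        assert (iv.start, iv.end, iv.strand) == (100, 170, "-")

    def test_duplicate_placement_ambiguous(self, small_genome, toy_annot):
        g = small_genome[:50] + toy_annot.sequence + small_genome[50:100] + toy_annot.sequence
        with pytest.raises(LocateError, match="ambiguous"):
            locate_precursor(toy_annot.sequence, {"chr1": g})

    def test_not_found(self, small_genome):
        with pytest.raises(LocateError, match="not found"):
            locate_precursor("ACGT" * 15, {"chr1": "T" * 500})

    def test_seeded_fallback_with_mismatches(self, small_genome, toy_annot):
        mutated = list(toy_annot.sequence)
        mutated[10] = "A" if mutated[10] != "A" else "C"
        mutated[40] = "A" if mutated[40] != "A" else "C"
        genome = {"chr1": small_genome[:100] + "".join(mutated) + small_genome[100:]}
        iv = locate_precursor(toy_annot.sequence, genome)
        assert (iv.start, iv.end) == (100, 170)


class TestSliceMaf:
    def test_query_inside_block(self, toy_blocks):
        sliced = slice_maf(toy_blocks, GenomeInterval("chr1", 12, 18))
        assert len(sliced) == 1
        ref = sliced[0].rows[0]
        assert ref.ungapped() == "GTAC--GT".replace("-", "")
        assert ref.start == 12 and ref.size == 6

    def test_no_overlap_empty(self, toy_blocks):
        assert slice_maf(toy_blocks, GenomeInterval("chr1", 60, 70)) == []

    def test_reference_gap_column_retained(self, toy_blocks):
        # ref columns 10..22 include the 2-col gap; slice across it
        sliced = slice_maf(toy_blocks, GenomeInterval("chr1", 14, 18))
        ref = sliced[0].rows[0]
        assert "-" in ref.text  # interior reference-gap columns kept
        assert ref.ungapped() == "ACGT"[0:4] and ref.size == 4

    def test_randomized_column_scan_oracle(self, rng):
        """Concatenated reference bases of the slice equal the genome
        substring, across random MAFs with indels."""
        for _ in range(40):
            cfg = SimulationConfig(
                seed=int(rng.integers(2**31)),
                genome_length=400,
                indel_rate=0.02,
                indel_in_precursors=True,
            )
            genome = make_genome(cfg, rng)
            aln = mutate_genome(genome, cfg, rng)
            blocks = make_maf(("ref", genome), [("spB", aln)], block_cols=90)
            s = int(rng.integers(0, len(genome) - 60))
            e = s + int(rng.integers(10, 60))
            sliced = slice_maf(blocks, GenomeInterval("chr1", s, e))
            got = "".join(b.rows[0].ungapped() for b in sliced)
            assert got == genome[s:e]
            assert got == reference_chars_in_region(blocks, s, e, "chr1")
            for b in sliced:
                b.validate()


class TestExtractHomologs:
    def _blocks(self):
        b1 = MafBlock([
            MafRow("ref.chr1", 0, 4, "+", 100, "ACGT"),
            MafRow("spB.chr1", 0, 4, "+", 90, "ACGA"),
            MafRow("spC.chr5", 7, 4, "+", 60, "AGGT"),
        ])
        b2 = MafBlock([
            MafRow("ref.chr1", 4, 4, "+", 100, "TTAA"),
            MafRow("spB.chr1", 4, 4, "+", 90, "TTAC"),
        ])
        return [b1, b2]

    def test_concatenation_and_padding(self):
        hs = extract_homologs(self._blocks(), ["spB", "spC"], GenomeInterval("chr1", 0, 8))
        assert hs.rows["ref"] == "ACGTTTAA"
        assert hs.rows["spB"] == "ACGATTAC"
        assert hs.rows["spC"] == "AGGT----"
        assert hs.coverage == {"ref": "complete", "spB": "complete", "spC": "partial"}

    def test_absent_species(self):
        hs = extract_homologs(self._blocks(), ["spB", "spD"], GenomeInterval("chr1", 0, 8))
        assert hs.coverage["spD"] == "absent" and hs.ungapped("spD") == ""

    def test_empty_slice_all_absent(self):
        hs = extract_homologs([], ["spB"], GenomeInterval("chr1", 0, 8))
        assert hs.coverage == {"spB": "absent"}

    def test_overlapping_blocks_rejected(self):
        b1, b2 = self._blocks()
        b2_overlap = MafBlock([
            MafRow("ref.chr1", 2, 4, "+", 100, "GTTT"),
            MafRow("spB.chr1", 2, 4, "+", 90, "GTTT"),
        ])
        with pytest.raises(MafFormatError, match="overlap"):
            extract_homologs([b1, b2_overlap], ["spB"], GenomeInterval("chr1", 0, 8))

    def test_column_count_consistent(self):
        hs = extract_homologs(self._blocks(), ["spB", "spC"], GenomeInterval("chr1", 0, 8))
        lengths = {len(r) for r in hs.rows.values()}
        assert lengths == {hs.ncols}


class TestScreenOrthologs:
    def test_simple_thresholds(self):
        dist = pd.DataFrame(
            [
                {"precursor": "a", "species": "s", "identity": 0.95, "coverage": 60},
                {"precursor": "b", "species": "s", "identity": 0.89, "coverage": 60},
            ]
        )
        expr = pd.DataFrame(
            [
                {"precursor": "a", "species": "s", "reads": 12},
                {"precursor": "b", "species": "s", "reads": 12},
            ]
        )
        kept, tally = screen_orthologs(dist, expr)
        assert list(kept["precursor"]) == ["a"]
        assert tally == {"retained": 1, "total": 2}

    def test_planted_240_candidates(self):
        """A candidate table planted with 93 passers out of 240 reports
        exactly 93 retained (39%)."""
        rows, expr = [], []
        for i in range(240):
            if i < 93:
                ident, cov, reads = 0.95, 60, 12
            elif i < 160:
                ident, cov, reads = 0.85, 60, 12  # fails identity
            elif i < 210:
                ident, cov, reads = 0.95, 45, 12  # fails coverage
            else:
                ident, cov, reads = 0.95, 60, 5  # fails read support
            rows.append({"precursor": f"p{i}", "species": "s", "identity": ident, "coverage": cov})
            expr.append({"precursor": f"p{i}", "species": "s", "reads": reads})
        kept, tally = screen_orthologs(pd.DataFrame(rows), pd.DataFrame(expr))
        assert tally == {"retained": 93, "total": 240}
        assert round(100 * tally["retained"] / tally["total"]) == 39
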