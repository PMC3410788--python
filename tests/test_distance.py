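"""K2P distances: column classification, the transform, region projection,
and parameter recovery on alignments with known rates."""

import math

import numpy as np
import pytest

from mirevokit.distance import (
    SubstitutionCounts,
    count_substitutions,
    estimate_distance,
    k2p,
    kmir_ks_ratio,
    region_columns,
    region_distances,
)
from mirevokit.maf import GenomeInterval, HomologSet
from mirevokit.simulate import SimulationConfig, mutate_genome, make_genome


class TestCountSubstitutions:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", (4, 0, 0, 0, 0)),
            ("ACGT", "GCGT", (3, 1, 0, 0, 0)),  # A<->G transition
            ("AC-T", "ACTT", (3, 0, 0, 1, 0)),
            ("ACGT", "ATGT", (3, 1, 0, 0, 0)),  # C<->T transition
            ("ACGT", "CCGT", (3, 0, 1, 0, 0)),  # A<->C transversion
            ("ANGT", "ACGT", (3, 0, 0, 0, 1)),
        ],
    )
    def test_column_classes(self, a, b, expected):
        c = count_substitutions(a, b)
        assert (c.matches, c.transitions, c.transversions, c.gap_columns, c.ambiguous_columns) == expected
        assert c.length == len(a)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_substitutions("ACGT", "ACG")

    def test_identity_complement_invariant(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            a = "".join(rng.choice(list("ACGT-"), size=n))
            b = "".join(rng.choice(list("ACGT-"), size=n))
            c = count_substitutions(a, b)
            if c.compared_columns:
                ident = c.matches / c.compared_columns
                subs = (c.transitions + c.transversions) / c.compared_columns
                assert ident + subs == pytest.approx(1.0)


class TestK2P:
    def test_zero_distance(self):
        assert k2p(0.0, 0.0) == 0.0

    def test_quarter_transitions(self):
        assert k2p(0.25, 0.0) == pytest.approx(-0.5 * math.log(0.5), abs=1e-9)
        assert k2p(0.25, 0.0) == pytest.approx(0.346574, abs=1e-6)

    def test_hand_evaluated_point(self):
        assert k2p(0.1, 0.05) == pytest.approx(0.170181, abs=1e-6)

    def test_saturation(self):
        assert k2p(0.5, 0.2) is None
        assert k2p(0.1, 0.5) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            k2p(-0.1, 0.0)

    def test_two_state_reduction_and_bounds(self):
        for P in np.linspace(0.0, 0.4, 17):
            assert k2p(P, 0.0) == pytest.approx(-0.5 * math.log(1 - 2 * P), abs=1e-12)
        prev = -1.0
        for P in np.linspace(0.0, 0.35, 15):
            k = k2p(P, 0.1)
            assert k >= P + 0.1 - 1e-12  # correction never below raw proportion
            assert k > prev  # monotone in P for fixed Q
            prev = k


class TestRegionDistances:
    def _homologs(self, ref_row, other_row, species="spB"):
        return HomologSet(
            "mir-x",
            "ref",
            {"ref": ref_row, species: other_row},
            {"ref": [], species: []},
            {"ref": "complete", species: "complete"},
            GenomeInterval("chr1", 0, len(ref_row.replace("-", ""))),
        )

    def test_identical_homolog_zero_everywhere(self, toy_annot):
        hs = self._homologs(toy_annot.sequence, toy_annot.sequence)
        table = region_distances(hs, toy_annot)
        assert set(table["region"]) == {"precursor", "mature_5p", "seed_5p", "mature_3p", "seed_3p"}
        assert (table["kmir"] == 0).all() and (table["identity"] == 1).all()

    def test_transitions_in_mature_region(self, toy_annot):
        seq = toy_annot.sequence
        s, e = toy_annot.mature_5p
        other = list(seq)
        # place 2 transitions at mature positions 10 and 12 (outside the seed)
        for pos in (s + 10, s + 12):
            other[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[other[pos]]
        hs = self._homologs(seq, "".join(other))
        table = region_distances(hs, toy_annot).set_index("region")
        assert table.loc["mature_5p", "P"] == pytest.approx(2 / 22)
        assert table.loc["precursor", "P"] == pytest.approx(2 / 70)
        assert table.loc["mature_5p", "kmir"] == pytest.approx(k2p(2 / 22, 0.0))
        assert table.loc["seed_5p", "kmir"] == 0.0

    def test_reference_gap_shifts_column_mapping(self, toy_annot):
        seq = toy_annot.sequence
        ref_row = seq[:1] + "-" + seq[1:]  # gap inserted before the mature start
        other_row = seq[:1] + "A" + seq[1:]
        hs = self._homologs(ref_row, other_row)
        table = region_distances(hs, toy_annot).set_index("region")
        # the inserted column sits before mature_5p: mature distance unaffected
        assert table.loc["mature_5p", "identity"] == 1.0
        assert table.loc["mature_5p", "coverage"] == 22

    def test_region_outside_precursor_rejected(self, toy_annot):
        with pytest.raises(ValueError):
            region_columns(toy_annot.sequence, 60, 80)

    def test_partial_homolog_computed_over_covered_columns(self, toy_annot):
        seq = toy_annot.sequence
        padded = "-" * 40 + seq[40:]
        hs = self._homologs(seq, padded)
        table = region_distances(hs, toy_annot).set_index("region")
        assert table.loc["precursor", "coverage"] == 30
        assert table.loc["mature_5p", "coverage"] == 0


class TestRecovery:
    def test_planted_rate_recovery_10kb(self):
        """On a 10 kb alignment mutated at p*=0.10, q*=0.05 the estimated
        proportions fall within 3 binomial SE and kmir within the
        propagated 3-SE band of the K2P transform."""
        cfg = SimulationConfig(seed=42, genome_length=10_000)
        genome = make_genome(cfg)
        aln = mutate_genome(genome, cfg, np.random.default_rng(43))
        ref_row, alt_row = aln.gapped_rows()
        c = count_substitutions(ref_row, alt_row)
        n = c.compared_columns
        p_star, q_star = cfg.transition_rate, cfg.transversion_rate
        se_p = math.sqrt(p_star * (1 - p_star) / n)
        se_q = math.sqrt(q_star * (1 - q_star) / n)
        P, Q = c.transitions / n, c.transversions / n
        assert abs(P - p_star) < 3 * se_p
        assert abs(Q - q_star) < 3 * se_q
        expected_k = k2p(p_star, q_star)
        dk_dp = 1 / (1 - 2 * p_star - q_star)
        dk_dq = 0.5 / (1 - 2 * p_star - q_star) + 0.5 / (1 - 2 * q_star)
        se_k = math.sqrt((dk_dp * se_p) ** 2 + (dk_dq * se_q) ** 2)
        assert abs(k2p(P, Q) - expected_k) < 3 * se_k


class TestRatio:
    def test_paper_style_ratio(self):
        # a region distance of 0.5 against a genome-wide Ks of 1.0
        assert kmir_ks_ratio(0.5, 1.0) == 0.5

    @pytest.mark.parametrize("kmir,ks,expected", [(0.0, 0.7, 0.0), (0.3, 0.2, 1.5)])
    def test_arithmetic(self, kmir, ks, expected):
        assert kmir_ks_ratio(kmir, ks) == pytest.approx(expected)

    def test_nonpositive_ks_rejected(self):
        with pytest.raises(ValueError):
            kmir_ks_ratio(0.5, 0.0)
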