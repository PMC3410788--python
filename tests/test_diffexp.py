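"""Poisson LRT, TPM normalization, BH correction, Yates chi-square, and
ortholog counting with arm projection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirevokit.annotate import PrecursorAnnotation
from mirevokit.diffexp import (
    count_orthologs,
    diff_table,
    poisson_lrt,
    project_arm,
    scatter_table,
    tpm,
    yates_chisq,
)
from mirevokit.maf import GenomeInterval, HomologSet
from mirevokit.smallrna import CollapsedRead


class TestTpm:
    @pytest.mark.parametrize("x,N,expected", [(50, 10**6, 50.0), (0, 100, 0.0), (3, 2 * 10**6, 1.5)])
    def test_values(self, x, N, expected):
        assert tpm(x, N) == pytest.approx(expected)

    def test_invalid_total(self):
        with pytest.raises(ValueError):
            tpm(1, 0)

    def test_scale_invariance(self):
        assert tpm(30, 1000) == pytest.approx(tpm(300, 10000))


class TestPoissonLrt:
    def test_equal_rates_null(self):
        res = poisson_lrt(10, 10**6, 10, 10**6)
        assert res.G == 0.0 and res.p == 1.0

    def test_closed_form_example(self):
        res = poisson_lrt(10, 10**6, 30, 10**6)
        assert res.G == pytest.approx(10.46496, abs=1e-5)
        assert res.p == pytest.approx(0.001217, abs=1e-6)

    def test_zero_count_convention(self):
        res = poisson_lrt(0, 10**6, 5, 10**6)
        assert res.G == pytest.approx(6.93147, abs=1e-5)
        assert res.p == pytest.approx(0.00847, abs=1e-5)

    def test_degenerate_both_zero(self):
        res = poisson_lrt(0, 100, 0, 100)
        assert res.p == 1.0 and res.degenerate

    def test_unequal_totals_equal_rates(self):
        res = poisson_lrt(20, 1000, 40, 2000)
        assert res.G == pytest.approx(0.0, abs=1e-12)

    @given(
        x1=st.integers(0, 500), x2=st.integers(0, 500),
        N1=st.integers(1000, 10**6), N2=st.integers(1000, 10**6),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_nonnegativity(self, x1, x2, N1, N2):
        a = poisson_lrt(x1, N1, x2, N2)
        b = poisson_lrt(x2, N2, x1, N1)
        assert a.G == pytest.approx(b.G, rel=1e-12, abs=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-12, abs=1e-12)
        assert a.G >= 0.0

    def test_null_calibration_quick(self, rng):
        """Type-I error near nominal at expected counts >= 10."""
        n = 3000
        x1 = rng.poisson(20, size=n)
        x2 = rng.poisson(20, size=n)
        rej = sum(poisson_lrt(int(a), 10**5, int(b), 10**5).p < 0.05 for a, b in zip(x1, x2))
        assert 0.03 < rej / n < 0.07


class TestYatesChisq:
    def test_method_comparison_table(self):
        chi2, p = yates_chisq([[93, 147], [66, 174]])
        assert p == pytest.approx(0.012, abs=5e-4)

    def test_identical_rows_null(self):
        chi2, p = yates_chisq([[50, 50], [50, 50]])
        assert chi2 == 0.0 and p == 1.0

    def test_hand_evaluated_diagonal(self):
        chi2, _ = yates_chisq([[20, 0], [0, 20]])
        assert chi2 == pytest.approx(36.1, abs=1e-6)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            yates_chisq([[0, 0], [5, 5]])


def _two_species_homologs(toy_annot, gap_shift=0):
    """Homolog set where spB's row optionally carries a 2-nt reference gap
    before the mature 5p arm (an insertion in spB)."""
    seq = toy_annot.sequence
    if gap_shift:
        ref_row = seq[:1] + "-" * gap_shift + seq[1:]
        spb_row = seq[:1] + "GG"[:gap_shift] + seq[1:]
    else:
        ref_row = spb_row = seq
    return HomologSet(
        toy_annot.precursor_id,
        "spA",
        {"spA": ref_row, "spB": spb_row},
        {"spA": [], "spB": []},
        {"spA": "complete", "spB": "complete"},
        GenomeInterval("chr1", 0, len(seq)),
    )


class TestCountOrthologs:
    def test_counts_on_5p_arm(self, toy_annot):
        hs = _two_species_homologs(toy_annot)
        s, e = toy_annot.mature_5p
        libs = {
            "spA": [CollapsedRead("spA_1_x7", toy_annot.sequence[s:e], 7)],
            "spB": [CollapsedRead("spB_1_x3", toy_annot.sequence[s:e], 3)],
        }
        expr = count_orthologs(libs, [hs], {toy_annot.precursor_id: toy_annot})
        a5 = expr[(expr.species == "spA") & (expr.arm == "5p")].iloc[0]
        assert a5.x == 7 and a5.N == 7

    def test_arm_projection_through_gap(self, toy_annot):
        hs = _two_species_homologs(toy_annot, gap_shift=2)
        s, e = project_arm(hs, "spB", *toy_annot.mature_5p)
        assert (s, e) == (toy_annot.mature_5p[0] + 2, toy_annot.mature_5p[1] + 2)
        spb_seq = hs.ungapped("spB")
        libs = {"spB": [CollapsedRead("spB_1_x4", spb_seq[s:e], 4)]}
        expr = count_orthologs(libs, [hs], {toy_annot.precursor_id: toy_annot})
        b5 = expr[(expr.species == "spB") & (expr.arm == "5p")].iloc[0]
        assert b5.x == 4

    def test_empty_library_rejected(self, toy_annot):
        hs = _two_species_homologs(toy_annot)
        with pytest.raises(ValueError, match="empty library"):
            count_orthologs({"spA": []}, [hs], {toy_annot.precursor_id: toy_annot})


class TestDiffTable:
    def _expr(self, rows):
        return pd.DataFrame(rows, columns=["precursor", "species", "arm", "x", "N"])

    def test_equal_rates_nothing_significant(self):
        rows = [
            (f"p{i}", sp, arm, 100, 10**6)
            for i in range(10)
            for sp in ("a", "b")
            for arm in ("5p", "3p")
        ]
        out = diff_table(self._expr(rows), "a", "b")
        assert not out["significant"].any()
        assert (out["q"] >= out["p"] - 1e-15).all()

    def test_single_arm_q_equals_p(self):
        rows = [("p1", "a", "5p", 10, 10**5), ("p1", "b", "5p", 40, 10**5)]
        out = diff_table(self._expr(rows), "a", "b")
        assert out.loc[0, "q"] == pytest.approx(out.loc[0, "p"])

    def test_planted_fold_changes_detected(self, rng):
        """10 planted 4-fold changes among 100 arms at depth 1e5 are all
        flagged; false flags stay within the BH expectation."""
        depth = 10**5
        rows = []
        for i in range(100):
            lam = 20
            x1 = int(rng.poisson(lam))
            x2 = int(rng.poisson(lam * (4 if i < 10 else 1)))
            rows.append((f"p{i}", "a", "5p", x1, depth))
            rows.append((f"p{i}", "b", "5p", x2, depth))
        out = diff_table(self._expr(rows), "a", "b").set_index("precursor")
        planted = [f"p{i}" for i in range(10)]
        assert out.loc[planted, "significant"].all()
        false_flags = out.drop(index=planted)["significant"].sum()
        assert false_flags <= 5  # BH at q<0.05 over ~10 true positives

    def test_scatter_columns(self):
        rows = [("p1", "a", "5p", 0, 10**6), ("p1", "b", "5p", 100, 10**6)]
        out = diff_table(self._expr(rows), "a", "b")
        sc = scatter_table(out)
        assert list(sc.columns) == ["precursor", "arm", "log2_tpm_1", "log2_tpm_2", "significant"]
        # zero count still plots: log2 of the one-read pseudocount TPM
        assert out.loc[0, "log2_tpm_1"] == pytest.approx(math.log2(1 / 10**6 * 1e6))

    def test_missing_species_rejected(self):
        rows = [("p1", "a", "5p", 5, 100)]
        with pytest.raises(ValueError):
            diff_table(self._expr(rows), "a", "b")
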