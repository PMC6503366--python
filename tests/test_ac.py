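import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import nbinom

import twolibde as tl


class TestPointProb:
    def test_zero_zero_equal_libraries(self):
        assert tl.ac_point_prob(0, 0, 1000, 1000) == pytest.approx(0.5, abs=1e-14)

    def test_zero_given_five(self):
        # (x+0)!/(x!0!) * 2^-(x+1) with x = 5
        assert tl.ac_point_prob(0, 5, 777, 777) == pytest.approx(2**-6, rel=1e-12)

    def test_normalisation(self):
        """p(y|x) sums to 1 over y (negative-binomial normalisation)."""
        total = sum(tl.ac_point_prob(y, 3, 1000, 2000) for y in range(2000))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_matches_negative_binomial_identity(self):
        """p(y|x) equals NegBin(y; x+1, N1/(N1+N2)) — an independent route."""
        n1, n2 = 3_000_000, 7_000_000
        for x, y in [(0, 0), (3, 10), (25, 4), (100, 130)]:
            expected = nbinom.pmf(y, x + 1, n1 / (n1 + n2))
            assert tl.ac_point_prob(y, x, n1, n2) == pytest.approx(
                expected, rel=1e-10)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            tl.ac_point_prob(-1, 0, 10, 10)


class TestAcPvalue:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            (0, 0, 1.0),        # S = 0.5 sits in the 2S branch
            (5, 0, 0.03125),    # 2 * 2^-6
            (0, 3, 0.125),      # 2 * (1 - (1 - 2^-4))
        ],
    )
    def test_closed_forms_equal_libraries(self, x, y, expected):
        assert tl.ac_pvalue(x, y, 10**6, 10**6) == pytest.approx(
            expected, abs=1e-12)

    def test_symmetry(self):
        """Swapping libraries and counts leaves the p-value unchanged."""
        for x, y in [(0, 7), (12, 3), (40, 55), (200, 170)]:
            a = tl.ac_pvalue(x, y, 1_000_000, 2_500_000)
            b = tl.ac_pvalue(y, x, 2_500_000, 1_000_000)
            assert a == pytest.approx(b, rel=1e-9)

    def test_monotone_away_from_x(self):
        """For N1 = N2 the p-value decreases as y moves away from x."""
        x, n = 20, 10**6
        up = [tl.ac_pvalue(x, y, n, n) for y in range(x, x + 30)]
        down = [tl.ac_pvalue(x, y, n, n) for y in range(x, -1, -1)]
        assert all(a >= b - 1e-12 for a, b in zip(up, up[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(down, down[1:]))

    def test_extreme_tail_keeps_relative_precision(self):
        """Deep-count p-values match the NB survival function far below eps."""
        x, y, n1, n2 = 1000, 2000, 10**7, 10**7
        s = nbinom.cdf(y, x + 1, n1 / (n1 + n2))
        oracle = 2 * (nbinom.sf(y, x + 1, n1 / (n1 + n2)) if s > 0.5 else s)
        assert tl.ac_pvalue(x, y, n1, n2) == pytest.approx(oracle, rel=1e-9)

    @given(
        x=st.integers(0, 60), y=st.integers(0, 60),
        ratio=st.sampled_from([1, 2, 5]),
    )
    def test_in_unit_interval(self, x, y, ratio):
        p = tl.ac_pvalue(x, y, 10**6, ratio * 10**6)
        assert 0.0 < p <= 1.0


class TestBhAdjust:
    def test_single_p(self):
        assert tl.bh_adjust([0.02], m_total=1) == pytest.approx([0.02])

    def test_step_up_minimum(self):
        out = tl.bh_adjust([0.01, 0.02, 0.03], m_total=3)
        assert out == pytest.approx([0.03, 0.03, 0.03])

    def test_matches_statsmodels(self):
        """Independent cross-check when m_total equals the list length."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=40)
        ours = tl.bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(theirs, rel=1e-12)

    def test_m_total_scales_ranks(self):
        # q_(i) = min_j>=i p_(j) * m_total / j
        out = tl.bh_adjust([0.001, 0.01], m_total=10)
        assert out == pytest.approx([0.01, 0.05])

    @given(p=st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_properties(self, p):
        adj = tl.bh_adjust(p)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in p rank

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        assert tl.bh_adjust(p)[perm] == pytest.approx(tl.bh_adjust(p[perm]))

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            tl.bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            tl.bh_adjust([0.1, 0.2], m_total=1)


class TestCallsAndSpecific:
    def test_threshold_logic(self):
        calls = tl.call_degs([1.5, 0.9, -2.0, -3.0],
                             [0.0005, 0.0005, 0.0005, 0.01])
        assert list(calls) == ["up", "not_significant", "down",
                               "not_significant"]

    def test_thresholds_inclusive(self):
        assert tl.call_degs(1.0, 0.001) == "up"
        assert tl.call_degs(-1.0, 0.001) == "down"

    def test_specific_classification(self):
        assert tl.detect_specific(0, 5) == "pregnant_only"
        assert tl.detect_specific(5, 0) == "nonpregnant_only"
        assert tl.detect_specific(3, 4) == "none"
        assert tl.detect_specific(0, 0) == "none"

    def test_specific_min_count(self):
        assert tl.detect_specific(0, 2, min_count=3) == "none"
        assert tl.detect_specific(0, 3, min_count=3) == "pregnant_only"


class TestDeTable:
    def test_silent_genes_excluded_and_sorted(self, tiny_table):
        de = tl.de_table(tiny_table)
        assert "g4" not in set(de["gene_id"])  # zero in both libraries
        assert len(de) == 3
        assert list(de["fdr"]) == sorted(de["fdr"])

    def test_specific_flags_present(self, tiny_table):
        de = tl.de_table(tiny_table).set_index("gene_id")
        assert de.loc["g2", "specific"] == "pregnant_only"
        assert de.loc["g3", "specific"] == "nonpregnant_only"
        assert de.loc["g1", "specific"] == "none"
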