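import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import twolibde as tl
from twolibde.datasets import (GOAT_OVARY_N, GOAT_OVARY_N_DEG,
                               GOAT_OVARY_TOTAL_PATHWAYS, goat_ovary_pathways)


def exact_upper_tail(m, M, n, N) -> Fraction:
    """Exact-rational P(X >= m) by direct enumeration."""
    denom = math.comb(N, n)
    num = sum(math.comb(M, i) * math.comb(N - M, n - i)
              for i in range(m, min(n, M) + 1))
    return Fraction(num, denom)


class TestHypergeomUpperP:
    def test_m_zero_is_one(self):
        assert tl.hypergeom_upper_p(0, 4, 5, 10) == 1.0

    def test_small_exact_value(self):
        # C(4,4)*C(6,1)/C(10,5) = 6/252
        assert tl.hypergeom_upper_p(4, 4, 5, 10) == pytest.approx(
            6 / 252, rel=1e-12)

    def test_published_goat_ovary_row(self):
        """The most enriched pathway of the goat-ovary comparison: 51 of
        1413 annotated DEGs fall in a 235-gene pathway (universe 22,885)."""
        p = tl.hypergeom_upper_p(51, 235, GOAT_OVARY_N_DEG, GOAT_OVARY_N)
        assert p == pytest.approx(2.05e-15, rel=5e-3)

    def test_matches_exact_enumeration(self):
        for N, M, n, m in [(20, 8, 6, 3), (45, 20, 11, 9), (60, 5, 30, 5),
                           (33, 16, 16, 1)]:
            assert tl.hypergeom_upper_p(m, M, n, N) == pytest.approx(
                float(exact_upper_tail(m, M, n, N)), rel=1e-12)

    def test_monotone_in_m(self):
        ps = [tl.hypergeom_upper_p(m, 50, 100, 1000) for m in range(0, 30)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_complementarity(self):
        from scipy.stats import hypergeom

        for m in (1, 5, 9):
            upper = tl.hypergeom_upper_p(m, 12, 15, 40)
            lower = hypergeom.cdf(m - 1, 40, 12, 15)
            assert upper + lower == pytest.approx(1.0, abs=1e-12)

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            tl.hypergeom_upper_p(5, 4, 10, 20)  # m > M
        with pytest.raises(ValueError):
            tl.hypergeom_upper_p(1, 25, 10, 20)  # M > N


class TestEnrich:
    def _annotations(self):
        pairs = [(f"g{i}", "T1") for i in range(10)]
        pairs += [(f"g{i}", "T2") for i in range(5, 50)]
        pairs += [(f"g{i}", "T3") for i in range(40, 100)]
        return tl.AnnotationSet.from_pairs(pairs)

    def test_counts_recomputed_from_annotation_set(self):
        ann = self._annotations()
        res = tl.enrich([f"g{i}" for i in range(10)], ann,
                        correction="bonferroni")
        row = res.set_index("term_id").loc["T1"]
        assert (row["N"], row["n"], row["M"], row["m"]) == (100, 10, 10, 10)

    def test_degenerate_all_degs_one_term(self):
        ann = tl.AnnotationSet.from_pairs([(f"g{i}", "only") for i in range(8)])
        res = tl.enrich([f"g{i}" for i in range(8)], ann)
        assert res.loc[0, "m"] == res.loc[0, "n"] == 8
        assert res.loc[0, "p_raw"] == pytest.approx(1.0)  # m = n = M = N

    def test_bonferroni_multiplies_by_tested_terms(self):
        ann = self._annotations()
        res = tl.enrich([f"g{i}" for i in range(10)], ann,
                        correction="bonferroni")
        t = len(res)
        assert res["p_corrected"].to_numpy() == pytest.approx(
            np.minimum(res["p_raw"].to_numpy() * t, 1.0))

    def test_bonferroni_single_term_equals_raw(self):
        ann = tl.AnnotationSet.from_pairs(
            [(f"g{i}", "T") for i in range(20)]
            + [(f"h{i}", "U") for i in range(20)])
        res = tl.enrich(["g0", "g1", "g2"], ann, correction="bonferroni")
        assert len(res) == 1  # U has m = 0 and is not tested
        assert res.loc[0, "p_corrected"] == pytest.approx(res.loc[0, "p_raw"])

    def test_degs_outside_universe_dropped(self):
        ann = self._annotations()
        res_with = tl.enrich(["g0", "g1", "nowhere"], ann)
        res_without = tl.enrich(["g0", "g1"], ann)
        assert res_with["n"].iloc[0] == res_without["n"].iloc[0] == 2

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            tl.enrich(["g1"], tl.AnnotationSet({}))

    def test_planted_term_ranks_first(self):
        cfg = tl.SimulationConfig(
            n_genes=2000, lib_size_a=10**6, lib_size_b=10**6, frac_de=0.1,
            frac_specific_a=0.0, frac_specific_b=0.0, dispersion=0.0, seed=5)
        table, truth = tl.generate_counts(cfg)
        ann, planted = tl.generate_annotations(
            truth, n_terms=40, enriched_terms=1, enrichment_strength=1.0,
            seed=6, term_size_range=(50, 50))
        de = tl.de_table(table)
        degs = de.loc[de["call"] != "not_significant", "gene_id"]
        res = tl.enrich(degs, ann, correction="bh")
        assert res.loc[0, "term_id"] == planted[0]


class TestKeggQvalues:
    # p-values of the significant pathways as reported for the goat-ovary
    # comparison, in rank order, BH-adjusted with the full 242-pathway total
    PRINTED_P = [2.05e-15, 1.88e-08, 1.87e-05, 2.00e-05, 2.70e-05, 4.89e-05,
                 8.77e-05, 0.000178193, 0.000587109, 0.000795974,
                 0.000920767, 0.001541861]

    def test_rank4_and_rank10_qvalues(self):
        q = tl.kegg_qvalues(self.PRINTED_P, GOAT_OVARY_TOTAL_PATHWAYS)
        assert q[3] == pytest.approx(1.21e-03, rel=5e-3)
        assert q[9] == pytest.approx(1.93e-02, rel=5e-3)

    def test_rank5_step_up_arithmetic(self):
        q = tl.kegg_qvalues(self.PRINTED_P, GOAT_OVARY_TOTAL_PATHWAYS)
        assert q[4] == pytest.approx(2.70e-05 * 242 / 5, rel=1e-2)

    def test_all_ones(self):
        assert tl.kegg_qvalues([1.0] * 5, 242) == pytest.approx([1.0] * 5)


class TestAnnotationIO:
    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("# comment\ng1\tT1\ng2\tT1\ng2\tT2\n")
        ann = tl.read_annotation_tsv(path)
        assert ann.universe == {"g1", "g2"}
        assert ann.term_size("T1") == 2

    def test_gmt(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("T1\tfirst set\tg1\tg2\nT2\tsecond\tg2\tg3\tg4\n")
        ann = tl.read_gmt(path)
        assert ann.term_size("T2") == 3
        assert ann.term_labels["T1"] == "first set"
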