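"""Fisher allele tests, per-gene summaries, impact filter, expression."""

from math import comb, log

import numpy as np
import pytest
from scipy import stats

from selsig.diff import (
    ContingencyTable2x2,
    expression_correlation,
    fisher_exact_2x2,
    gene_diff_summary,
    impact_filter,
    significance_stars,
)
from selsig.diff import test_gene_loci as run_gene_locus_tests
from selsig.gio import ConsequenceRecord, GeneSpan, Impact, TpmMatrix, Variant
from selsig.synth import simulate_tpm

from conftest import make_matrix


def _fisher_oracle(a, b, c, d):
    """Log-factorial hypergeometric enumeration, written independently."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def logp(x):
        return (log(comb(r1, x)) + log(comb(r2, c1 - x)) - log(comb(n, c1)))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = logp(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = logp(x)
        if lp <= obs + 1e-12:
            total += np.exp(lp)
    return min(1.0, total)


TABLE3 = {
    # gene, locus -> (LI table vs commercial, LI table vs Chinese, stars)
    ("NR6A1", "1:265347265"): ((17, 5, 600, 10), (17, 5, 139, 593), "***", "***"),
    ("PAPPA2", "9:118365925"): ((16, 6, 610, 0), (16, 6, 660, 72), "***", "*"),
    ("PIK3C2B", "9:65126980"): ((17, 5, 485, 125), (17, 5, 692, 40), "", "**"),
}


class TestFisher:
    def test_identical_rows_give_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_strong_differentiation_below_0_001(self):
        # the focal-breed vs Chinese-indigenous allele table at the vertebra
        # locus: 17/5 vs 139/593 is differentiated at p < 0.001
        assert fisher_exact_2x2([[17, 5], [139, 593]]) < 0.001

    @pytest.mark.parametrize("table", [
        (16, 6, 610, 0), (17, 5, 139, 593), (20, 2, 593, 17),
        (22, 0, 607, 3), (3, 0, 0, 5), (1, 1, 1, 1), (0, 7, 7, 0),
    ])
    def test_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
            _fisher_oracle(a, b, c, d), rel=1e-9)

    @pytest.mark.parametrize("table", [
        (16, 6, 610, 0), (17, 5, 692, 40), (9, 3, 2, 8), (50, 0, 0, 50),
    ])
    def test_matches_scipy(self, table):
        a, b, c, d = table
        assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
            stats.fisher_exact([[a, b], [c, d]]).pvalue, abs=1e-12)

    def test_empty_margin_convention(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0
        assert fisher_exact_2x2([[0, 3], [0, 4]]) == 1.0

    def test_symmetry_under_row_and_column_swap(self, rng):
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
            p = fisher_exact_2x2([[a, b], [c, d]])
            assert fisher_exact_2x2([[c, d], [a, b]]) == pytest.approx(p, rel=1e-9)
            assert fisher_exact_2x2([[b, a], [d, c]]) == pytest.approx(p, rel=1e-9)

    def test_published_allele_tables_reproduce_stars(self):
        for (gene, locus), (t_com, t_chn, star_com, star_chn) in TABLE3.items():
            for t, star in ((t_com, star_com), (t_chn, star_chn)):
                p = fisher_exact_2x2([[t[0], t[1]], [t[2], t[3]]])
                assert significance_stars(p) >= star or len(significance_stars(p)) >= len(star)

    def test_type_one_error_band(self, rng):
        # null: both populations at the same frequency, n=50 diploids each
        m = 2000
        p0 = rng.uniform(0.2, 0.8, size=m)
        hits = 0
        for k in range(m):
            x = int(rng.binomial(100, p0[k]))
            y = int(rng.binomial(100, p0[k]))
            hits += fisher_exact_2x2([[x, 100 - x], [y, 100 - y]]) < 0.05
        assert 0.02 <= hits / m <= 0.07


class TestGeneLoci:
    def test_identical_populations_nothing_significant(self, rng):
        calls = np.tile(rng.integers(0, 3, size=(10, 1)), (1, 40)).astype(np.int8)
        gm = make_matrix(calls, pops=["A"] * 20 + ["B"] * 20)
        span = GeneSpan("g", "G1", "1", 1, 10**6)
        res = run_gene_locus_tests(gm, span, "A", "B")
        assert len(res) == 10
        assert not any(r.significant for r in res)

    def test_planted_shift_detected(self, rng):
        # 3 of 10 loci at 0.1 vs 0.9 ALT frequency, 50 diploids per pop
        pa = np.full(10, 0.5)
        pb = np.full(10, 0.5)
        pa[:3], pb[:3] = 0.1, 0.9
        calls = np.concatenate([
            rng.binomial(2, pa[:, None], (10, 50)),
            rng.binomial(2, pb[:, None], (10, 50)),
        ], axis=1).astype(np.int8)
        gm = make_matrix(calls, pops=["A"] * 50 + ["B"] * 50)
        res = run_gene_locus_tests(gm, GeneSpan("g", "G1", "1", 1, 10**6), "A", "B")
        assert all(res[i].significant for i in range(3))

    def test_span_restricts_loci(self):
        calls = np.zeros((5, 4), dtype=np.int8)
        calls[:, 0] = 1
        gm = make_matrix(calls, pops=["A", "A", "B", "B"])
        res = run_gene_locus_tests(gm, GeneSpan("g", "G1", "1", 1500, 3500), "A", "B")
        assert [r.pos for r in res] == [2000, 3000]

    def test_allele_margin_is_twice_diploid_count(self, rng):
        calls = rng.integers(0, 3, size=(4, 11 + 8)).astype(np.int8)
        gm = make_matrix(calls, pops=["LI"] * 11 + ["EU"] * 8)
        res = run_gene_locus_tests(gm, GeneSpan("g", "G1", "1", 1, 10**6), "LI", "EU")
        for r in res:
            assert r.table.a + r.table.b == 22


class TestGeneSummary:
    def _res(self, gene, n_sig, n_tot, pair):
        from selsig.diff import LocusTestResult

        return [
            LocusTestResult(chrom="1", pos=i + 1, gene_name=gene, pair=pair,
                            table=ContingencyTable2x2(1, 1, 1, 1),
                            p_value=0.01 if i < n_sig else 0.5)
            for i in range(n_tot)
        ]

    def test_zero_significant(self):
        s = gene_diff_summary(self._res("G", 0, 10, ("A", "B")), [])
        assert s["G"].prop_sig_pair1 == 0.0

    def test_direction_comparison(self):
        n = 2000
        s = gene_diff_summary(
            self._res("NR6A1", 989, n, ("LI", "COM")),
            self._res("NR6A1", 525, n, ("LI", "CHN")),
        )["NR6A1"]
        assert s.prop_sig_pair1 > s.prop_sig_pair2

    def test_props_match_recount(self, rng):
        from selsig.diff import LocusTestResult

        res1, res2 = [], []
        for i in range(50):
            gene = f"G{rng.integers(3)}"
            for res in (res1, res2):
                res.append(LocusTestResult(
                    chrom="1", pos=i + 1, gene_name=gene, pair=("A", "B"),
                    table=ContingencyTable2x2(1, 1, 1, 1),
                    p_value=float(rng.random())))
        summ = gene_diff_summary(res1, res2)
        for gene, s in summ.items():
            n1 = sum(1 for r in res1 if r.gene_name == gene and r.p_value < 0.05)
            n_loci = len({r.pos for r in res1 + res2 if r.gene_name == gene})
            assert s.n_sig_pair1 == n1
            assert s.n_loci == n_loci


class TestImpactFilter:
    def _record(self, gene, impact, pos):
        return ConsequenceRecord(
            variant=Variant("1", pos, "A", "G"), gene_name=gene,
            consequence="x", impact=impact)

    def test_published_missense_counts(self):
        # 11 moderate missense rows -> per-gene counts 1 / 7 / 3
        rows = [("NR6A1", 1)] + [("PAPPA2", i + 2) for i in range(7)] \
             + [("PIK3C2B", i + 10) for i in range(3)]
        records = [self._record(g, Impact.MODERATE, p) for g, p in rows]
        _, counts = impact_filter(records)
        assert counts == {"NR6A1": 1, "PAPPA2": 7, "PIK3C2B": 3}

    def test_all_low_filtered_out(self):
        records = [self._record("G", Impact.LOW, i + 1) for i in range(5)]
        kept, counts = impact_filter(records)
        assert kept == [] and counts == {}

    def test_mixed_matches_bruteforce(self, rng):
        impacts = list(Impact)
        records = [self._record("G", impacts[rng.integers(4)], i + 1)
                   for i in range(40)]
        kept, _ = impact_filter(records, min_impact=Impact.MODERATE)
        assert kept == [r for r in records if r.impact >= Impact.MODERATE]
        assert Impact.MODIFIER < Impact.LOW < Impact.MODERATE < Impact.HIGH


class TestExpressionCorrelation:
    def _tpm(self, x, y, tissue="ileum"):
        n = len(x)
        samples = [f"s{i}" for i in range(n)]
        return TpmMatrix(genes=["A", "B"], samples=samples,
                         tissue_of={s: tissue for s in samples},
                         tpm=np.vstack([x, y]))

    def test_perfect_correlation(self):
        x = np.arange(1.0, 11.0)
        res = expression_correlation(self._tpm(x, x), [("A", "B")])
        assert len(res) == 1
        assert res[0].r == pytest.approx(1.0)

    def test_matches_closed_form_pearson(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 4, 5, 9])
        r_hand = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        res = expression_correlation(self._tpm(x, y), [("A", "B")], alpha=1.0)
        assert res[0].r == pytest.approx(r_hand, abs=1e-12)

    def test_constant_gene_dropped(self):
        x = np.arange(1.0, 11.0)
        res = expression_correlation(self._tpm(x, np.full(10, 3.0)), [("A", "B")],
                                     alpha=1.0)
        assert res == []

    def test_retention_monotone_in_alpha(self, rng):
        tpm = simulate_tpm(["A", "B", "C"], ["ileum", "lung"], 0.5,
                           n_per_tissue=20, seed=4)
        pairs = [("A", "B"), ("A", "C"), ("B", "C")]
        kept = [len(expression_correlation(tpm, pairs, alpha=a))
                for a in (0.01, 0.05, 0.5, 1.0)]
        assert kept == sorted(kept)
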