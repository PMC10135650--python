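"""EM haplotype frequencies, D' confidence intervals, and block calling."""

import itertools

import numpy as np
import pytest

from selsig.gio import GenotypeMatrix, Variant
from selsig.ldblocks import (
    BlockConfig,
    HaploBlock,
    UninformativePairError,
    dprime_ci,
    em_from_genotype_counts,
    em_hap_freqs,
    ld_stats,
    find_blocks,
    pair_ld,
    top_blocks,
)
from selsig.synth import SimConfig, simulate_cohort

from conftest import make_matrix


def _geno_counts(a, b):
    c = np.zeros((3, 3), dtype=np.int64)
    np.add.at(c, (np.asarray(a), np.asarray(b)), 1)
    return c


def _loglik(counts, freqs):
    pAB, pAb, paB, pab = freqs
    probs = {
        (0, 0): pAB**2, (0, 1): 2 * pAB * pAb, (0, 2): pAb**2,
        (1, 0): 2 * pAB * paB, (1, 1): 2 * pAB * pab + 2 * pAb * paB,
        (1, 2): 2 * pAb * pab, (2, 0): paB**2, (2, 1): 2 * paB * pab,
        (2, 2): pab**2,
    }
    ll = 0.0
    for (i, j), pr in probs.items():
        if counts[i, j]:
            if pr <= 0:
                return -np.inf
            ll += counts[i, j] * np.log(pr)
    return ll


def _grid_search(counts, step=1e-3):
    """Exhaustive simplex search maximizing the same multinomial likelihood."""
    best, best_ll = None, -np.inf
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    for pAB in ticks:
        for pAb in np.arange(0.0, 1.0 - pAB + step / 2, step):
            for paB in np.arange(0.0, 1.0 - pAB - pAb + step / 2, step):
                f = (pAB, pAb, paB, 1.0 - pAB - pAb - paB)
                ll = _loglik(counts, f)
                if ll > best_ll:
                    best, best_ll = f, ll
    return best


def test_em_equals_direct_counting_without_double_hets():
    # genotypes with no (1,1) class: haplotypes are fully determined
    a = [0, 0, 2, 2, 1, 0, 2]
    b = [0, 2, 0, 2, 0, 1, 2]
    counts = _geno_counts(a, b)
    freqs = em_from_genotype_counts(counts)
    # direct gamete counting over the unambiguous genotype classes
    tally = np.zeros(4)
    for ga, gb in zip(a, b):
        pairs = {(0, 0): [(0, 0), (0, 0)], (0, 2): [(0, 1), (0, 1)],
                 (2, 0): [(1, 0), (1, 0)], (2, 2): [(1, 1), (1, 1)],
                 (1, 0): [(0, 0), (1, 0)], (0, 1): [(0, 0), (0, 1)],
                 (1, 2): [(0, 1), (1, 1)], (2, 1): [(1, 0), (1, 1)]}[(ga, gb)]
        for h in pairs:
            tally[{(0, 0): 0, (0, 1): 1, (1, 0): 2, (1, 1): 3}[h]] += 1
    assert np.allclose(freqs, tally / tally.sum(), atol=1e-9)
    assert sum(freqs) == pytest.approx(1.0, abs=1e-9)


def test_em_matches_simplex_grid_search(rng):
    # 20 samples including 6 double heterozygotes
    a = [1] * 6 + [0, 0, 0, 2, 2, 1, 1, 0, 2, 1, 0, 2, 0, 1]
    b = [1] * 6 + [0, 2, 0, 2, 0, 0, 2, 1, 1, 0, 0, 2, 1, 2]
    counts = _geno_counts(a, b)
    em = em_from_genotype_counts(counts)
    grid = _grid_search(counts, step=1e-2)  # coarse pass
    # refine around the coarse optimum at 1e-3 resolution
    assert _loglik(counts, em) >= _loglik(counts, grid) - 1e-6
    fine = _grid_search_local(counts, grid, coarse=1e-2, step=1e-3)
    assert np.allclose(em, fine, atol=2e-3)


def _grid_search_local(counts, center, coarse, step):
    best, best_ll = None, -np.inf
    c0, c1, c2, _ = center
    r = np.arange(-coarse, coarse + step / 2, step)
    for dA in r:
        pAB = c0 + dA
        if pAB < 0:
            continue
        for dB in r:
            pAb = c1 + dB
            if pAb < 0 or pAB + pAb > 1:
                continue
            for dC in r:
                paB = c2 + dC
                pab = 1 - pAB - pAb - paB
                if paB < 0 or pab < 0:
                    continue
                ll = _loglik(counts, (pAB, pAb, paB, pab))
                if ll > best_ll:
                    best, best_ll = (pAB, pAb, paB, pab), ll
    return best


def test_em_likelihood_nondecreasing(rng):
    a = rng.binomial(2, 0.5, 30)
    b = rng.binomial(2, 0.4, 30)
    counts = _geno_counts(a, b)
    lls = []
    freqs = np.full(4, 0.25)
    for _ in range(50):
        lls.append(_loglik(counts, freqs))
        # one manual EM step reusing the package's routine with max_iter=1
        freqs = np.array(em_from_genotype_counts(counts, tol=0.0, max_iter=len(lls)))
    assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


def test_complete_association_gives_dprime_one():
    counts = np.zeros((3, 3), dtype=int)
    counts[0, 0] = counts[2, 2] = 40
    counts[1, 1] = 20  # double hets consistent with AB/ab only
    freqs = em_from_genotype_counts(counts)
    assert freqs[1] == pytest.approx(0.0, abs=1e-6)
    assert freqs[2] == pytest.approx(0.0, abs=1e-6)
    D, dprime, r2 = ld_stats(freqs)
    assert dprime == pytest.approx(1.0)
    assert r2 == pytest.approx(1.0, abs=1e-6)


def test_r2_equals_dosage_correlation_for_homozygous_calls(rng):
    # with only homozygous calls each individual's two gametes are identical,
    # so the gametic r^2 from counted haplotypes equals the squared dosage
    # correlation exactly (with heterozygotes the within-individual gamete
    # pairing breaks this identity on finite samples)
    a = rng.choice([0, 2], size=40)
    b = np.where(rng.random(40) < 0.8, a, rng.choice([0, 2], size=40))
    counts = _geno_counts(a, b)
    freqs = em_from_genotype_counts(counts)
    _, _, r2 = ld_stats(freqs)
    r = np.corrcoef(a, b)[0, 1]
    assert r2 == pytest.approx(r * r, abs=1e-9)


class TestDprimeCI:
    def test_complete_ld_large_n(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0] = counts[2, 2] = 100
        counts[1, 1] = 50
        _, lo, hi = dprime_ci(counts)
        assert lo >= 0.70 and hi >= 0.98

    def test_independent_snps_rarely_look_strong(self, rng):
        bad = 0
        for _ in range(20):
            a = rng.binomial(2, 0.5, 200)
            b = rng.binomial(2, 0.5, 200)
            _, _, hi = dprime_ci(_geno_counts(a, b))
            bad += hi >= 0.9
        assert bad <= 2  # ci_high < 0.9 with probability > 0.9

    def test_tiny_sample_wide_ci(self):
        counts = _geno_counts([0, 1, 2, 0], [0, 1, 2, 1])
        _, lo, hi = dprime_ci(counts)
        assert hi - lo > 0.5

    def test_monomorphic_pair_excluded(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0] = 10  # locus 1 fixed REF
        with pytest.raises(UninformativePairError):
            dprime_ci(counts)

    def test_no_joint_observation(self):
        with pytest.raises(UninformativePairError):
            em_from_genotype_counts(np.zeros((3, 3), dtype=int))


class TestBlocks:
    def test_two_snps_complete_ld_one_block(self, rng):
        hap = rng.binomial(1, 0.5, 100)
        calls = np.vstack([hap + rng.binomial(1, 0.5, 100) * 0, hap]).astype(np.int8)
        # two identical dosage rows in complete LD, 1 kb apart
        base = (hap + rng.binomial(1, 0.5, 100)).clip(0, 2)
        calls = np.vstack([base, base]).astype(np.int8)
        gm = make_matrix(calls, positions=[1000, 2000])
        blocks = find_blocks(gm)
        assert len(blocks) == 1
        assert blocks[0].snp_indices == (0, 1)

    def test_planted_regions_recovered_within_one_snp(self):
        plants = [("1", 1_000_000, 1_050_000, 2),
                  ("1", 2_000_000, 2_050_000, 2),
                  ("1", 3_000_000, 3_050_000, 2)]
        cfg = SimConfig(seed=5, n_snps=400, chrom_lengths={"1": 4_000_000},
                        n_pops=1, n_per_pop=(100,), fst_target=0.0,
                        block_plants=plants)
        gm, _ = simulate_cohort(cfg)
        blocks = find_blocks(gm)
        pos = gm.pos
        matched = 0
        for chrom, s, e, _ in plants:
            inside = np.flatnonzero((pos >= s) & (pos <= e))
            want = (int(pos[inside[0]]), int(pos[inside[-1]]))
            for b in blocks:
                lo_off = abs(np.searchsorted(pos, b.start_bp) - inside[0])
                hi_off = abs(np.searchsorted(pos, b.end_bp) - inside[-1])
                if lo_off <= 1 and hi_off <= 1:
                    matched += 1
                    break
        assert matched == 3

    def test_block_cap_enforced(self, rng):
        # perfectly associated SNPs 250 kb apart cannot form a block
        base = rng.binomial(2, 0.5, 80).astype(np.int8)
        gm = make_matrix(np.vstack([base, base]), positions=[1_000, 251_000])
        assert find_blocks(gm) == []
        for b in find_blocks(make_matrix(np.vstack([base, base]),
                                         positions=[1_000, 201_000])):
            assert b.length_bp <= 200_001

    def test_reported_blocks_pass_internal_audit(self):
        cfg = SimConfig(seed=9, n_snps=300, chrom_lengths={"1": 2_000_000},
                        n_pops=1, n_per_pop=(80,), fst_target=0.0,
                        block_plants=[("1", 500_000, 560_000, 3),
                                      ("1", 1_200_000, 1_260_000, 4)])
        gm, _ = simulate_cohort(cfg)
        bc = BlockConfig()
        blocks = find_blocks(gm, bc)
        assert blocks, "expected at least one block"
        for b in blocks:
            idx = b.snp_indices
            n_strong = n_recomb = 0
            for i, j in itertools.combinations(idx, 2):
                try:
                    _, lo, hi = dprime_ci(_geno_counts(gm.calls[i], gm.calls[j]))
                except UninformativePairError:
                    continue
                if lo >= bc.strong_ci_low and hi >= bc.strong_ci_high:
                    n_strong += 1
                elif hi < bc.recomb_ci_high:
                    n_recomb += 1
            assert n_strong / (n_strong + n_recomb) >= bc.min_strong_fraction


class TestTopBlocks:
    def _mk(self, lengths):
        return [HaploBlock("1", 1, l, (0, 1)) for l in lengths]

    def test_unique_lengths_select_one(self):
        blocks = self._mk(range(1000, 101000, 1000))
        top = top_blocks(blocks, 0.01)
        assert len(top) == 1 and top[0].length_bp == 100_000

    def test_cutoff_ties_all_included(self):
        lengths = list(range(1, 296)) + [500] * 5
        top = top_blocks(self._mk(lengths), 0.01)
        # k = ceil(3.0) = 3 but five blocks tie the cutoff length
        assert len(top) == 5

    def test_length_convention_ranks_table_rows(self):
        # 31,422,148..31,622,148 spans 200,001 bp under end-start+1
        rows = [("8", 15_865_991, 16_065_990), ("8", 16_265_054, 16_465_054),
                ("13", 126_316_668, 126_516_664), ("14", 31_422_148, 31_622_148)]
        blocks = [HaploBlock(c, s, e, (0, 1)) for c, s, e in rows]
        lengths = sorted({b.length_bp for b in blocks}, reverse=True)
        assert lengths == [200_001, 200_000, 199_997]
        assert blocks[3].length_bp == 200_001

    def test_empty_input(self):
        assert top_blocks([]) == []


def test_pair_ld_invariants(rng):
    gm, _ = simulate_cohort(SimConfig(seed=13, n_snps=30,
                                      chrom_lengths={"1": 100_000}))
    p = pair_ld(gm, 0, 1)
    assert sum(p.hap_freqs) == pytest.approx(1.0, abs=1e-9)
    assert 0 <= p.dprime_ci_low <= p.dprime_ci_high <= 1
    assert 0 <= p.r2 <= 1
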