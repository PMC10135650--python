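"""Pairwise LD (r^2, D' with likelihood-profile CI) and haplotype blocks.

Haplotype frequencies for a SNP pair are estimated from unphased diploid
genotypes by EM: every two-locus genotype except the double heterozygote
resolves to a unique haplotype pair; double heterozygotes are split between
the cis (AB/ab) and trans (Ab/aB) phasings by their posterior under the
current frequency estimate.

Blocks follow the confidence-interval definition: a pair is "strong LD"
when the 90% CI on D' has lower bound >= 0.70 and upper bound >= 0.98, and
"strong recombination" when the upper bound is < 0.90. A candidate interval
is a block when its outermost pair is strong LD and at least 95% of its
informative pairs are strong LD; overlaps are resolved greedily by
descending bp length. Block length may not exceed the kb cap plus 1 bp
(end - start + 1 of two SNPs exactly cap apart).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .gio import MISSING, GenotypeMatrix

# allele convention: "A"/"B" = REF at each locus, dosage counts ALT;
# hap_freqs order is (p_AB, p_Ab, p_aB, p_ab) with uppercase = REF.


@dataclass(frozen=True)
class PairLD:
    snp_i: int
    snp_j: int
    hap_freqs: tuple[float, float, float, float]
    D: float
    D_prime: float
    r2: float
    dprime_ci_low: float
    dprime_ci_high: float


@dataclass(frozen=True)
class HaploBlock:
    chrom: str
    start_bp: int
    end_bp: int
    snp_indices: tuple[int, ...]

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class BlockConfig:
    max_block_kb: float = 200.0
    strong_ci_low: float = 0.70
    strong_ci_high: float = 0.98
    recomb_ci_high: float = 0.90
    min_strong_fraction: float = 0.95
    ci_grid_points: int = 101
    em_tol: float = 1e-8
    em_max_iter: int = 1000


class UninformativePairError(ValueError):
    """No jointly observed samples, or a monomorphic member SNP."""


def _pair_genotype_counts(gm_calls: np.ndarray, snp_i: int, snp_j: int) -> np.ndarray:
    """3x3 table of joint dosage counts over samples non-missing at both."""
    a, b = gm_calls[snp_i], gm_calls[snp_j]
    ok = (a != MISSING) & (b != MISSING)
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (a[ok].astype(int), b[ok].astype(int)), 1)
    return counts


def em_hap_freqs(
    gm: GenotypeMatrix | np.ndarray,
    snp_i: int,
    snp_j: int,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[float, float, float, float]:
    """EM estimate of the four haplotype frequencies (p_AB, p_Ab, p_aB, p_ab).

    Maximizes the multinomial likelihood of the unphased two-locus genotype
    counts. Converges when the max absolute frequency change drops below
    ``tol``. With no double heterozygotes, this is exact haplotype counting.
    """
    calls = gm.calls if isinstance(gm, GenotypeMatrix) else gm
    counts = _pair_genotype_counts(calls, snp_i, snp_j)
    return em_from_genotype_counts(counts, tol=tol, max_iter=max_iter)


def em_from_genotype_counts(counts: np.ndarray, tol: float = 1e-8,
                            max_iter: int = 1000) -> tuple[float, float, float, float]:
    n = counts.sum()
    if n == 0:
        raise UninformativePairError("no jointly observed samples")
    # fixed haplotype contributions from the 8 unambiguous genotype classes;
    # dosage g counts ALT ("a"/"b" lowercase), so g=0 is hom REF.
    fixed = np.zeros(4)  # AB, Ab, aB, ab
    contrib = {
        (0, 0): ((0, 2),), (0, 1): ((0, 1), (1, 1)), (0, 2): ((1, 2),),
        (1, 0): ((0, 1), (2, 1)), (1, 2): ((1, 1), (3, 1)),
        (2, 0): ((2, 2),), (2, 1): ((2, 1), (3, 1)), (2, 2): ((3, 2),),
    }
    for (gi, gj), haps in contrib.items():
        for h, m in haps:
            fixed[h] += m * counts[gi, gj]
    n_dh = counts[1, 1]  # double heterozygotes: AB/ab or Ab/aB

    freqs = np.full(4, 0.25)
    for _ in range(max_iter):
        cis = freqs[0] * freqs[3]
        trans = freqs[1] * freqs[2]
        tot = cis + trans
        w = cis / tot if tot > 0 else 0.5
        new = fixed.copy()
        new[0] += n_dh * w
        new[3] += n_dh * w
        new[1] += n_dh * (1 - w)
        new[2] += n_dh * (1 - w)
        new /= 2.0 * n
        if np.max(np.abs(new - freqs)) < tol:
            freqs = new
            break
        freqs = new
    return tuple(float(f) for f in freqs)


def ld_stats(hap_freqs) -> tuple[float, float, float]:
    """(D, D_prime, r2) from haplotype frequencies (p_AB, p_Ab, p_aB, p_ab)."""
    pAB, pAb, paB, pab = hap_freqs
    pA = pAB + pAb  # REF freq at locus 1
    pB = pAB + paB  # REF freq at locus 2
    D = pAB - pA * pB
    if D > 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    D_prime = abs(D) / d_max if d_max > 0 else 0.0
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = D * D / denom if denom > 0 else 0.0
    return D, min(D_prime, 1.0), min(r2, 1.0)


def _loglik_of_freqs(counts: np.ndarray, freqs: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 genotype counts under hap freqs."""
    pAB, pAb, paB, pab = np.clip(freqs, 0.0, 1.0)
    # genotype-class probabilities under random union of gametes
    probs = np.empty((3, 3))
    probs[0, 0] = pAB ** 2
    probs[0, 1] = 2 * pAB * pAb
    probs[0, 2] = pAb ** 2
    probs[1, 0] = 2 * pAB * paB
    probs[1, 1] = 2 * pAB * pab + 2 * pAb * paB
    probs[1, 2] = 2 * pAb * pab
    probs[2, 0] = paB ** 2
    probs[2, 1] = 2 * paB * pab
    probs[2, 2] = pab ** 2
    with np.errstate(divide="ignore"):
        lp = np.log(probs)
    mask = counts > 0
    if np.any(np.isneginf(lp[mask])):
        return -np.inf
    return float((counts[mask] * lp[mask]).sum())


def dprime_ci(
    counts: np.ndarray,
    grid_points: int = 101,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[float, float, float]:
    """(D_prime, ci_low, ci_high): 90% likelihood-profile CI on |D'|.

    The profile fixes the EM-estimated allele frequencies and sweeps |D'|
    over ``grid_points`` equidistant values in [0, 1] on the MLE's sign of D;
    the normalized likelihood over the grid is accumulated, with the lower /
    upper bounds at cumulative mass 5% / 95%.
    """
    counts = np.asarray(counts)
    freqs = np.array(em_from_genotype_counts(counts, tol=tol, max_iter=max_iter))
    pA = freqs[0] + freqs[1]
    pB = freqs[0] + freqs[2]
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise UninformativePairError("monomorphic SNP in pair")
    D_hat, dprime_hat, _ = ld_stats(freqs)
    sign = 1.0 if D_hat >= 0 else -1.0
    if sign > 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))

    grid = np.linspace(0.0, 1.0, grid_points)
    D = sign * grid * d_max
    f = np.clip(
        np.stack([
            pA * pB + D,
            pA * (1 - pB) - D,
            (1 - pA) * pB - D,
            (1 - pA) * (1 - pB) + D,
        ], axis=1),
        0.0, 1.0,
    )  # (grid, 4): pAB, pAb, paB, pab
    pAB, pAb, paB, pab = f[:, 0], f[:, 1], f[:, 2], f[:, 3]
    probs = np.empty((grid_points, 3, 3))
    probs[:, 0, 0] = pAB**2
    probs[:, 0, 1] = 2 * pAB * pAb
    probs[:, 0, 2] = pAb**2
    probs[:, 1, 0] = 2 * pAB * paB
    probs[:, 1, 1] = 2 * pAB * pab + 2 * pAb * paB
    probs[:, 1, 2] = 2 * pAb * pab
    probs[:, 2, 0] = paB**2
    probs[:, 2, 1] = 2 * paB * pab
    probs[:, 2, 2] = pab**2
    mask = counts > 0
    with np.errstate(divide="ignore"):
        lp = np.log(probs[:, mask])
    logliks = np.where(
        np.isneginf(lp).any(axis=1), -np.inf, (counts[mask] * lp).sum(axis=1)
    )
    logliks -= logliks.max()
    lik = np.exp(logliks)
    lik /= lik.sum()
    cdf = np.cumsum(lik)
    lo = float(grid[int(np.searchsorted(cdf, 0.05, side="left"))])
    hi = float(grid[int(np.searchsorted(cdf, 0.95, side="left"))])
    return dprime_hat, lo, hi


def pair_ld(gm: GenotypeMatrix, snp_i: int, snp_j: int,
            cfg: BlockConfig | None = None) -> PairLD:
    """Full pairwise LD summary (EM frequencies, D, D', r^2, D' CI)."""
    cfg = cfg or BlockConfig()
    counts = _pair_genotype_counts(gm.calls, snp_i, snp_j)
    freqs = em_from_genotype_counts(counts, tol=cfg.em_tol, max_iter=cfg.em_max_iter)
    D, dprime, r2 = ld_stats(freqs)
    dprime, lo, hi = dprime_ci(counts, grid_points=cfg.ci_grid_points,
                               tol=cfg.em_tol, max_iter=cfg.em_max_iter)
    return PairLD(snp_i, snp_j, freqs, D, dprime, r2, lo, hi)


_STRONG, _RECOMB, _AMBIG, _SKIP = 1, 2, 0, -1


def _classify_pairs(gm: GenotypeMatrix, lo: int, hi: int, cfg: BlockConfig,
                    max_span_bp: int) -> np.ndarray:
    """Pair classes for all i<j in rows [lo, hi) within max_span_bp."""
    n = hi - lo
    pos = gm.pos[lo:hi]
    cls = np.full((n, n), _SKIP, dtype=np.int8)
    for a in range(n):
        for b in range(a + 1, n):
            if pos[b] - pos[a] > max_span_bp:
                break
            try:
                counts = _pair_genotype_counts(gm.calls, lo + a, lo + b)
                _, ci_lo, ci_hi = dprime_ci(counts, grid_points=cfg.ci_grid_points,
                                            tol=cfg.em_tol, max_iter=cfg.em_max_iter)
            except UninformativePairError:
                continue
            if ci_lo >= cfg.strong_ci_low and ci_hi >= cfg.strong_ci_high:
                cls[a, b] = _STRONG
            elif ci_hi < cfg.recomb_ci_high:
                cls[a, b] = _RECOMB
            else:
                cls[a, b] = _AMBIG
    return cls


def find_blocks(gm: GenotypeMatrix, cfg: BlockConfig | None = None) -> list[HaploBlock]:
    """Confidence-interval haplotype blocks under the kb cap, per chromosome."""
    cfg = cfg or BlockConfig()
    max_span = int(cfg.max_block_kb * 1000)
    blocks: list[HaploBlock] = []
    for chrom, sl in gm.chrom_slices().items():
        lo, hi = sl.start, sl.stop
        n = hi - lo
        if n < 2:
            continue
        pos = gm.pos[lo:hi]
        cls = _classify_pairs(gm, lo, hi, cfg, max_span)
        candidates: list[tuple[int, int, int]] = []  # (length_bp, a, b)
        for a in range(n):
            for b in range(a + 1, n):
                if pos[b] - pos[a] > max_span:
                    break
                if cls[a, b] != _STRONG:
                    continue
                sub = cls[a : b + 1, a : b + 1]
                n_strong = int((sub == _STRONG).sum())
                n_recomb = int((sub == _RECOMB).sum())
                informative = n_strong + n_recomb
                if informative and n_strong / informative >= cfg.min_strong_fraction:
                    candidates.append((int(pos[b] - pos[a] + 1), a, b))
        # greedy by descending bp length; ties by leftmost start then smaller span
        candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
        taken: list[tuple[int, int]] = []
        for length, a, b in candidates:
            if any(not (b < ta or a > tb) for ta, tb in taken):
                continue
            taken.append((a, b))
            blocks.append(
                HaploBlock(
                    chrom=chrom,
                    start_bp=int(pos[a]),
                    end_bp=int(pos[b]),
                    snp_indices=tuple(range(lo + a, lo + b + 1)),
                )
            )
    blocks.sort(key=lambda blk: (blk.chrom, blk.start_bp))
    return blocks


def top_blocks(blocks: list[HaploBlock], top_fraction: float = 0.01) -> list[HaploBlock]:
    """Longest top-percentile blocks; ties at the cutoff length all included."""
    if not blocks:
        return []
    k = int(ceil(top_fraction * len(blocks)))
    lengths = sorted((b.length_bp for b in blocks), reverse=True)
    cutoff = lengths[k - 1]
    return [b for b in blocks if b.length_bp >= cutoff]


def write_blocks_tsv(blocks: list[HaploBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tblock_start\tblock_end\tblock_length_bp\tn_snps\n")
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start_bp}\t{b.end_bp}\t{b.length_bp}\t{b.n_snps}\n")
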