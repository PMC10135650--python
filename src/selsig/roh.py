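"""Runs of homozygosity: per-individual detection, length classes, islands.

Detection follows the sliding-window convention of the widely used
``--homozyg`` scan: windows of ``window_snps`` consecutive SNPs are scored
as homozygous "hits" when they contain at most ``max_het_per_window``
heterozygous and ``max_missing_per_window`` missing calls; each SNP is
assigned the fraction of overlapping scored windows that are hits; SNPs
whose fraction reaches ``hit_proportion`` are eligible; maximal eligible
runs, split at inter-SNP gaps of ``max_gap_bp`` or more, become segments if
they satisfy the length, SNP-count and density thresholds.

An ROH island is a run of consecutive SNPs whose population-level ROH
incidence falls in the top percentile.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .gio import MISSING, GenotypeMatrix


@dataclass
class RohConfig:
    window_snps: int = 50
    max_het_per_window: int = 3
    max_missing_per_window: int = 1
    min_density_bp_per_snp: int = 100_000
    max_gap_bp: int = 250_000
    min_length_bp: int = 1_000_000
    min_snps: int = 50
    hit_proportion: float = 0.05

    def __post_init__(self) -> None:
        if self.window_snps < 1:
            raise ValueError("window_snps must be >= 1")
        if not 0.0 < self.hit_proportion <= 1.0:
            raise ValueError("hit_proportion must lie in (0, 1]")


@dataclass(frozen=True)
class RohSegment:
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass(frozen=True)
class RohIsland:
    chrom: str
    start_bp: int
    end_bp: int
    snp_indices: tuple[int, ...]  # contiguous row indices in the matrix
    peak_incidence: float

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def detect_roh(gm: GenotypeMatrix, sample_id: str, cfg: RohConfig | None = None) -> list[RohSegment]:
    """Detect ROH segments for one individual, per chromosome."""
    cfg = cfg or RohConfig()
    col = gm.samples.index(sample_id)
    segments: list[RohSegment] = []
    for chrom, sl in gm.chrom_slices().items():
        calls = gm.calls[sl, col]
        pos = gm.pos[sl]
        segments.extend(
            RohSegment(sample_id, chrom, int(pos[a]), int(pos[b]), b - a + 1)
            for a, b in _segment_runs(calls, pos, cfg)
        )
    return segments


def _segment_runs(calls: np.ndarray, pos: np.ndarray, cfg: RohConfig) -> list[tuple[int, int]]:
    """Eligible-run extraction on one chromosome; returns (first, last) SNP index pairs."""
    n = calls.size
    w = cfg.window_snps
    if n < w:
        # chromosome shorter than one window: nothing scored
        return []
    het = (calls == 1).astype(np.int64)
    mis = (calls == MISSING).astype(np.int64)
    # window sums via cumulative sums; window t covers SNPs [t, t+w-1]
    ch = np.concatenate([[0], np.cumsum(het)])
    cm = np.concatenate([[0], np.cumsum(mis)])
    nw = n - w + 1
    t = np.arange(nw)
    hits = ((ch[t + w] - ch[t]) <= cfg.max_het_per_window) & (
        (cm[t + w] - cm[t]) <= cfg.max_missing_per_window
    )
    # SNP s is covered by windows max(0, s-w+1) .. min(nw-1, s)
    chit = np.concatenate([[0], np.cumsum(hits.astype(np.int64))])
    s = np.arange(n)
    w_lo = np.maximum(0, s - w + 1)
    w_hi = np.minimum(nw - 1, s)
    n_windows = w_hi - w_lo + 1
    n_hits = chit[w_hi + 1] - chit[w_lo]
    frac = n_hits / n_windows
    eligible = frac >= cfg.hit_proportion

    runs: list[tuple[int, int]] = []
    a = None
    for i in range(n):
        if eligible[i]:
            if a is None:
                a = i
            elif pos[i] - pos[i - 1] >= cfg.max_gap_bp:
                runs.append((a, i - 1))
                a = i
        elif a is not None:
            runs.append((a, i - 1))
            a = None
    if a is not None:
        runs.append((a, n - 1))

    out = []
    for a, b in runs:
        length = int(pos[b] - pos[a] + 1)
        n_snps = b - a + 1
        if (
            length >= cfg.min_length_bp
            and n_snps >= cfg.min_snps
            and length / n_snps <= cfg.min_density_bp_per_snp
        ):
            out.append((a, b))
    return out


def detect_roh_all(gm: GenotypeMatrix, cfg: RohConfig | None = None,
                   samples: list[str] | None = None) -> list[RohSegment]:
    """ROH segments for every sample (or the listed subset)."""
    cfg = cfg or RohConfig()
    out: list[RohSegment] = []
    for s in samples or gm.samples:
        out.extend(detect_roh(gm, s, cfg))
    return out


def classify_roh(segments: list[RohSegment]) -> dict[str, dict[str, float]]:
    """Counts and percentage shares per length class 1-5 Mb / 5-10 Mb / >10 Mb.

    Class boundaries are [1, 5), [5, 10), [10, inf) Mb; shares sum to 100.
    """
    mb = 1_000_000
    counts = {"1-5Mb": 0, "5-10Mb": 0, ">10Mb": 0}
    for seg in segments:
        if seg.length_bp < 5 * mb:
            counts["1-5Mb"] += 1
        elif seg.length_bp < 10 * mb:
            counts["5-10Mb"] += 1
        else:
            counts[">10Mb"] += 1
    total = sum(counts.values())
    return {
        cls: {
            "count": c,
            "percent": (100.0 * c / total) if total else 0.0,
        }
        for cls, c in counts.items()
    }


def roh_incidence(segments: list[RohSegment], gm: GenotypeMatrix) -> np.ndarray:
    """Fraction of individuals whose ROH cover each SNP.

    incidence[s] = (# individuals with >= 1 segment covering SNP s) / (# individuals),
    where the denominator is the number of samples in the matrix.
    """
    n_ind = gm.n_samples
    covered = np.zeros((n_ind, gm.n_variants), dtype=bool)
    sample_row = {s: i for i, s in enumerate(gm.samples)}
    pos = gm.pos
    slices = gm.chrom_slices()
    for seg in segments:
        sl = slices.get(seg.chrom)
        if sl is None:
            continue
        p = pos[sl]
        lo = sl.start + int(np.searchsorted(p, seg.start_bp, side="left"))
        hi = sl.start + int(np.searchsorted(p, seg.end_bp, side="right"))
        covered[sample_row[seg.sample_id], lo:hi] = True
    return covered.sum(axis=0) / n_ind


def selection_size(n: int, top_fraction: float) -> int:
    """Top-percentile selection size: ceiling(top_fraction * n)."""
    return int(ceil(top_fraction * n))


def top_threshold(values: np.ndarray, top_fraction: float) -> float:
    """Value of the k-th largest entry, k = ceiling(top_fraction * n)."""
    k = selection_size(values.size, top_fraction)
    return float(np.sort(values)[::-1][k - 1])


def call_islands(incidence: np.ndarray, gm: GenotypeMatrix,
                 top_fraction: float = 0.01) -> list[RohIsland]:
    """Merge top-percentile-incidence SNPs into ROH islands.

    The cutoff is the k-th largest incidence over all SNPs,
    k = ceiling(top_fraction * n_snps); every SNP tying the cutoff is
    selected. SNPs with zero incidence are never selected (an SNP that never
    occurs in any ROH cannot anchor an island), so an all-zero incidence
    vector yields no islands. Selected SNPs that are consecutive rows of the
    matrix on the same chromosome merge into one island.
    """
    incidence = np.asarray(incidence, dtype=float)
    if incidence.size != gm.n_variants:
        raise ValueError("incidence length != number of variants")
    if not np.any(incidence > 0):
        return []
    cutoff = top_threshold(incidence, top_fraction)
    selected = (incidence >= cutoff) & (incidence > 0)

    islands: list[RohIsland] = []
    pos = gm.pos
    for chrom, sl in gm.chrom_slices().items():
        idx = np.flatnonzero(selected[sl]) + sl.start
        if idx.size == 0:
            continue
        # split where row indices are not consecutive
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for a, b in zip(np.concatenate([[0], breaks + 1]),
                        np.concatenate([breaks, [idx.size - 1]])):
            run = idx[a : b + 1]
            islands.append(
                RohIsland(
                    chrom=chrom,
                    start_bp=int(pos[run[0]]),
                    end_bp=int(pos[run[-1]]),
                    snp_indices=tuple(int(i) for i in run),
                    peak_incidence=float(incidence[run].max()),
                )
            )
    return islands


def write_segments_tsv(segments: list[RohSegment], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tn_snps\tlength_kb\n")
        for s in segments:
            fh.write(f"{s.sample_id}\t{s.chrom}\t{s.start_bp}\t{s.end_bp}\t"
                     f"{s.n_snps}\t{s.length_bp / 1000:.3f}\n")


def write_islands_tsv(islands: list[RohIsland], path, bed_path=None) -> None:
    """Write islands as 1-based inclusive TSV and, optionally, BED (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based inclusive\n")
        fh.write("chrom\tstart\tend\tn_snps\tpeak_incidence\n")
        for i in islands:
            fh.write(f"{i.chrom}\t{i.start_bp}\t{i.end_bp}\t{len(i.snp_indices)}\t"
                     f"{i.peak_incidence:.4f}\n")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for i in islands:
                fh.write(f"{i.chrom}\t{i.start_bp - 1}\t{i.end_bp}\n")
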