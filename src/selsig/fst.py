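"""Per-SNP two-population Weir-Cockerham F_ST and top-percentile selection.

The estimator is the r=2 variance-components form: with per-population
non-missing diploid counts n_i, ALT frequencies p_i and observed
heterozygote frequencies h_i,

    n_bar = mean(n_i)                     n_c  = (r*n_bar - sum n_i^2/(r*n_bar)) / (r-1)
    p_bar = sum(n_i p_i) / (r*n_bar)      s^2  = sum n_i (p_i - p_bar)^2 / ((r-1) n_bar)
    h_bar = sum(n_i h_i) / (r*n_bar)

    a = n_bar/n_c * [ s^2 - (p_bar(1-p_bar) - (r-1)/r s^2 - h_bar/4) / (n_bar-1) ]
    b = n_bar/(n_bar-1) * [ p_bar(1-p_bar) - (r-1)/r s^2 - (2 n_bar - 1)/(4 n_bar) h_bar ]
    c = h_bar / 2

and theta = a / (a + b + c), undefined when the denominator is zero
(site monomorphic in both populations). A ratio-of-sums estimate over many
loci is sum(a) / sum(a + b + c).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .gio import MISSING, GenotypeMatrix, Variant


@dataclass(frozen=True)
class FstRecord:
    variant: Variant
    pop_pair: tuple[str, str]
    n1: int
    n2: int
    p1: float
    p2: float
    h1: float
    h2: float
    a: float
    b: float
    c: float
    theta: float | None  # None when a+b+c == 0 or a population too small


@dataclass
class ScanResult:
    records: list[FstRecord]
    threshold: float
    selected: list[int]  # indices into records


def _pop_site_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n, p_alt, h_obs) per site for one population's dosage sub-matrix."""
    ok = calls != MISSING
    n = ok.sum(axis=1)
    alt = np.where(ok, calls, 0).sum(axis=1)
    het = ((calls == 1) & ok).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def wc_components(
    n1, p1, h1, n2, p2, h2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized a, b, c components of the two-population estimator."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    return a, b, c


def wc_fst(gm: GenotypeMatrix, popA: str, popB: str) -> list[FstRecord]:
    """Per-SNP Weir-Cockerham records for a population pair.

    Sites where either population has fewer than 2 non-missing samples, or
    that are monomorphic in both populations (a+b+c == 0), get theta None.
    """
    colsA = gm.sample_idx(popA)
    colsB = gm.sample_idx(popB)
    n1, p1, h1 = _pop_site_stats(gm.calls[:, colsA])
    n2, p2, h2 = _pop_site_stats(gm.calls[:, colsB])
    usable = (n1 >= 2) & (n2 >= 2)

    a = np.full(gm.n_variants, np.nan)
    b = np.full(gm.n_variants, np.nan)
    c = np.full(gm.n_variants, np.nan)
    if usable.any():
        a[usable], b[usable], c[usable] = wc_components(
            n1[usable], p1[usable], h1[usable], n2[usable], p2[usable], h2[usable]
        )
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)

    records = []
    for i, v in enumerate(gm.variants):
        ok = usable[i] and denom[i] != 0 and np.isfinite(theta[i])
        records.append(
            FstRecord(
                variant=v,
                pop_pair=(popA, popB),
                n1=int(n1[i]),
                n2=int(n2[i]),
                p1=float(p1[i]) if n1[i] else np.nan,
                p2=float(p2[i]) if n2[i] else np.nan,
                h1=float(h1[i]) if n1[i] else np.nan,
                h2=float(h2[i]) if n2[i] else np.nan,
                a=float(a[i]),
                b=float(b[i]),
                c=float(c[i]),
                theta=float(theta[i]) if ok else None,
            )
        )
    return records


def ratio_of_sums(records: list[FstRecord]) -> float:
    """Multi-locus estimate sum(a) / sum(a+b+c) over defined records."""
    a = sum(r.a for r in records if r.theta is not None)
    abc = sum(r.a + r.b + r.c for r in records if r.theta is not None)
    if abc == 0:
        raise ValueError("no defined records")
    return a / abc


def top_snps(records: list[FstRecord], top_fraction: float = 0.01) -> ScanResult:
    """Select the top-percentile theta records; cutoff ties all included."""
    defined = [(i, r.theta) for i, r in enumerate(records) if r.theta is not None]
    if not defined:
        raise ValueError("no defined F_ST records to rank")
    thetas = np.array([t for _, t in defined])
    k = int(ceil(top_fraction * len(defined)))
    cutoff = float(np.sort(thetas)[::-1][k - 1])
    selected = [i for i, t in defined if t >= cutoff]
    return ScanResult(records=records, threshold=cutoff, selected=selected)


def write_fst_tsv(records: list[FstRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tn1\tn2\tp1\tp2\ttheta\n")
        for r in records:
            t = f"{r.theta:.6f}" if r.theta is not None else "NA"
            fh.write(f"{r.variant.chrom}\t{r.variant.pos}\t{r.n1}\t{r.n2}\t"
                     f"{r.p1:.4f}\t{r.p2:.4f}\t{t}\n")


def manhattan_plot(records: list[FstRecord], path, threshold: float | None = None) -> None:
    """Convenience Manhattan-style scatter of per-SNP theta (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs, ys, colors = [], [], []
    offset = 0.0
    chroms: dict[str, list[int]] = {}
    for r in records:
        chroms.setdefault(r.variant.chrom, []).append(r.variant.pos)
    chrom_offset = {}
    for c, ps in chroms.items():
        chrom_offset[c] = offset
        offset += max(ps) + 1
    for k, r in enumerate(records):
        if r.theta is None:
            continue
        xs.append(chrom_offset[r.variant.chrom] + r.variant.pos)
        ys.append(r.theta)
        colors.append(hash(r.variant.chrom) % 2)
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.scatter(xs, ys, s=3, c=colors, cmap="tab10")
    if threshold is not None:
        ax.axhline(threshold, color="red", lw=1)
    ax.set_xlabel("genome position")
    ax.set_ylabel(r"$F_{ST}$ ($\theta$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
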