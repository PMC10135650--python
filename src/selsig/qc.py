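"""Genotype quality control and LD pruning.

The filter order is fixed: (1) keep autosomal variants only, (2) drop
variants by missingness, (3) drop samples by missingness (recomputed on the
surviving variants), (4) drop variants by MAF (recomputed on the surviving
samples). LD pruning slides a window of ``prune_window_snps`` SNPs advancing
by ``prune_step_snps`` and greedily removes one SNP of each pair whose
dosage correlation exceeds ``prune_max_r2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .gio import MISSING, PIG_AUTOSOMES, GenotypeMatrix


class EmptyAfterQcError(RuntimeError):
    """Raised when quality control removes every sample or every variant."""


@dataclass
class QcConfig:
    max_variant_missing: float = 0.1
    max_sample_missing: float = 0.1
    min_maf: float = 0.05
    autosomes_only: bool = True
    autosomes: frozenset[str] = PIG_AUTOSOMES
    prune_window_snps: int = 50
    prune_step_snps: int = 10
    prune_max_r2: float = 0.4

    def __post_init__(self) -> None:
        for f in (self.max_variant_missing, self.max_sample_missing, self.min_maf):
            if not 0.0 <= f <= 1.0:
                raise ValueError("missingness/MAF thresholds must lie in [0, 1]")
        if not self.prune_window_snps >= self.prune_step_snps >= 1:
            raise ValueError("need prune_window_snps >= prune_step_snps >= 1")


@dataclass
class QcReport:
    """Per-step drop counts, in application order."""

    n_variants_in: int = 0
    n_samples_in: int = 0
    n_dropped_non_autosomal: int = 0
    n_dropped_variant_missing: int = 0
    n_dropped_sample_missing: int = 0
    n_dropped_maf: int = 0
    n_variants_out: int = 0
    n_samples_out: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def maf(calls: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per variant row, from non-missing calls only.

    Monomorphic-with-no-data rows get MAF 0.
    """
    calls = np.atleast_2d(calls)
    ok = calls != MISSING
    n = ok.sum(axis=1)
    alt = np.where(ok, calls, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), 0.0)
    return np.minimum(p, 1.0 - p)


def filter_genotypes(gm: GenotypeMatrix, cfg: QcConfig) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the four QC steps in their fixed order; returns matrix + report."""
    rep = QcReport(n_variants_in=gm.n_variants, n_samples_in=gm.n_samples)

    # (1) autosomes
    if cfg.autosomes_only:
        keep_v = np.array([v.chrom in cfg.autosomes for v in gm.variants])
    else:
        keep_v = np.ones(gm.n_variants, dtype=bool)
    rep.n_dropped_non_autosomal = int((~keep_v).sum())
    vi = np.flatnonzero(keep_v)
    calls = gm.calls[vi]

    # (2) variant missingness
    miss_frac = (calls == MISSING).mean(axis=1) if calls.size else np.zeros(len(vi))
    ok = miss_frac <= cfg.max_variant_missing
    rep.n_dropped_variant_missing = int((~ok).sum())
    vi = vi[ok]
    calls = gm.calls[vi]

    # (3) sample missingness on surviving variants
    if len(vi):
        smiss = (calls == MISSING).mean(axis=0)
    else:
        smiss = np.zeros(gm.n_samples)
    keep_s = smiss <= cfg.max_sample_missing
    rep.n_dropped_sample_missing = int((~keep_s).sum())
    si = np.flatnonzero(keep_s)
    if si.size == 0:
        raise EmptyAfterQcError("all samples removed by missingness filter")
    calls = calls[:, si]

    # (4) MAF on surviving samples
    if len(vi):
        ok = maf(calls) >= cfg.min_maf
    else:
        ok = np.zeros(0, dtype=bool)
    rep.n_dropped_maf = int((~ok).sum())
    vi = vi[ok]

    out = gm.subset(variant_idx=vi, sample_idx=si)
    rep.n_variants_out = out.n_variants
    rep.n_samples_out = out.n_samples
    return out, rep


def dosage_r2(calls: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of two dosage rows, pairwise-complete."""
    a, b = calls[i], calls[j]
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return r * r


def ld_prune(gm: GenotypeMatrix, cfg: QcConfig) -> np.ndarray:
    """Window-based LD pruning; returns sorted retained variant indices.

    Per chromosome, windows of ``prune_window_snps`` SNPs advance by
    ``prune_step_snps``. Within a window, pairs still retained are visited in
    (i, j) index order; if r^2 > ``prune_max_r2`` the member with the smaller
    MAF is removed (tie: the later position). The scan restarts within the
    window until no violating pair remains, so the result is deterministic.
    """
    removed = np.zeros(gm.n_variants, dtype=bool)
    mafs = maf(gm.calls)
    for _, sl in gm.chrom_slices().items():
        lo, hi = sl.start, sl.stop
        start = lo
        while start < hi:
            stop = min(start + cfg.prune_window_snps, hi)
            _prune_window(gm.calls, mafs, removed, start, stop, cfg.prune_max_r2)
            if stop == hi:
                break
            start += cfg.prune_step_snps
    return np.flatnonzero(~removed)


def _prune_window(calls, mafs, removed, start, stop, max_r2) -> None:
    idx = [k for k in range(start, stop) if not removed[k]]
    changed = True
    while changed:
        changed = False
        for a in range(len(idx)):
            i = idx[a]
            if removed[i]:
                continue
            for b in range(a + 1, len(idx)):
                j = idx[b]
                if removed[j]:
                    continue
                if dosage_r2(calls, i, j) > max_r2:
                    # drop smaller-MAF member; tie -> later position (j)
                    drop = i if mafs[i] < mafs[j] else j
                    removed[drop] = True
                    changed = True
                    if drop == i:
                        break
            if changed:
                break
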