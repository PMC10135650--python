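"""Synthetic cohorts with planted, machine-readable truth.

The genotype generator follows the Balding-Nichols model: each locus draws
an ancestral frequency p ~ Uniform(0.05, 0.95); each population's frequency
is Beta(p(1-F)/F, (1-p)(1-F)/F) around it (F > 0; F = 0 reuses p), and
individual genotypes are Binomial(2, population frequency), independent
across loci. F directly parameterizes the expected differentiation the
F_ST scan estimates. On this exchangeable background three kinds of signal
can be planted with exact truth records: autozygous (ROH) tracts copied
from a single founder haplotype, strong-LD regions built from a small
founder-haplotype pool, and per-locus allele-frequency outliers.

Background loci are independent (no LD), so block and ROH false positives
are directly measurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .gio import GenotypeMatrix, TpmMatrix, Variant, ConsequenceRecord, GeneSpan, Impact

_BASES = np.array(list("ACGT"))

#: Default cohort: three diverged breed groups at one-tenth of a typical
#: multi-breed resequencing panel (focal, other-indigenous, commercial).
DEFAULT_POPS = ("LI", "CN", "EU")
DEFAULT_N_PER_POP = (22, 37, 31)


@dataclass
class SimConfig:
    seed: int
    n_pops: int = 3
    n_per_pop: tuple[int, ...] | int = DEFAULT_N_PER_POP
    pop_names: tuple[str, ...] | None = None
    n_snps: int = 5000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 50_000_000, "2": 50_000_000}
    )
    fst_target: float = 0.2
    missing_rate: float = 0.0
    roh_plants: list[tuple[str, str, int, int]] = field(default_factory=list)
    # (chrom, start, end, n_founder_haplotypes)
    block_plants: list[tuple[str, int, int, int]] = field(default_factory=list)
    # (chrom, pos, (freq per pop))
    outlier_plants: list[tuple[str, int, tuple[float, ...]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must lie in [0, 1)")
        if isinstance(self.n_per_pop, int):
            self.n_per_pop = (self.n_per_pop,) * self.n_pops
        if len(self.n_per_pop) != self.n_pops:
            raise ValueError("n_per_pop length != n_pops")
        if self.pop_names is None:
            self.pop_names = (
                DEFAULT_POPS[: self.n_pops]
                if self.n_pops <= len(DEFAULT_POPS)
                else tuple(f"pop{i + 1}" for i in range(self.n_pops))
            )
        for chrom, pos, freqs in self.outlier_plants:
            if len(freqs) != self.n_pops:
                raise ValueError("outlier plant needs one frequency per population")
            if not all(0.0 <= f <= 1.0 for f in freqs):
                raise ValueError("plant frequencies must lie in [0, 1]")
            if chrom not in self.chrom_lengths or not 1 <= pos <= self.chrom_lengths[chrom]:
                raise ValueError(f"outlier plant outside genome: {chrom}:{pos}")
        for chrom, start, end, _ in self.block_plants:
            if start > end or end > self.chrom_lengths.get(chrom, 0):
                raise ValueError(f"block plant outside genome: {chrom}:{start}-{end}")
        for _, chrom, start, end in self.roh_plants:
            if start > end or end > self.chrom_lengths.get(chrom, 0):
                raise ValueError(f"ROH plant outside genome: {chrom}:{start}-{end}")


@dataclass
class TruthTable:
    roh_plants: list[tuple[str, str, int, int]]
    block_plants: list[tuple[str, int, int, int]]
    outlier_plants: list[tuple[str, int, tuple[float, ...]]]
    pop_names: tuple[str, ...]
    #: realized per-population ALT frequency per variant, (n_snps, n_pops)
    pop_freqs: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def to_json(self, path) -> None:
        d = asdict(self)
        d["pop_freqs"] = np.round(self.pop_freqs, 6).tolist()
        with open(path, "w") as fh:
            json.dump(d, fh)


def _chrom_key(chrom: str):
    return (int(chrom), "") if chrom.isdigit() else (10**9, chrom)


def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Draw a cohort; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n_pops = cfg.n_pops
    sizes = cfg.n_per_pop
    pop_names = cfg.pop_names
    n_total = int(sum(sizes))
    samples = [
        f"{pop_names[p]}_{i + 1:03d}" for p in range(n_pops) for i in range(sizes[p])
    ]
    pop_of = {
        s: pop_names[p] for p, s in zip(
            np.repeat(np.arange(n_pops), sizes), samples
        )
    }
    pop_col = np.repeat(np.arange(n_pops), sizes)

    # --- genome layout: planted outlier positions are guaranteed SNPs ------
    chroms_sorted = sorted(cfg.chrom_lengths, key=_chrom_key)
    total_len = sum(cfg.chrom_lengths.values())
    planted_pos: dict[str, set[int]] = {c: set() for c in chroms_sorted}
    for chrom, pos, _ in cfg.outlier_plants:
        planted_pos[chrom].add(pos)
    variants: list[Variant] = []
    chrom_arr: list[str] = []
    n_left = cfg.n_snps - sum(len(v) for v in planted_pos.values())
    if n_left < 0:
        raise ValueError("more outlier plants than n_snps")
    pos_by_chrom: dict[str, np.ndarray] = {}
    remaining = n_left
    for k, chrom in enumerate(chroms_sorted):
        clen = cfg.chrom_lengths[chrom]
        if k == len(chroms_sorted) - 1:
            n_c = remaining
        else:
            n_c = int(round(n_left * clen / total_len))
            n_c = min(n_c, remaining)
        remaining -= n_c
        pool = rng.choice(clen, size=min(clen, n_c + len(planted_pos[chrom]) + 50),
                          replace=False) + 1
        pool = [int(p) for p in pool if int(p) not in planted_pos[chrom]][:n_c]
        allpos = np.array(sorted(set(pool) | planted_pos[chrom]), dtype=np.int64)
        pos_by_chrom[chrom] = allpos
    for chrom in chroms_sorted:
        for p in pos_by_chrom[chrom]:
            ref, alt = rng.choice(4, size=2, replace=False)
            variants.append(Variant(chrom=chrom, pos=int(p),
                                    ref=str(_BASES[ref]), alt=str(_BASES[alt])))
            chrom_arr.append(chrom)
    n_snps = len(variants)
    pos_arr = np.array([v.pos for v in variants], dtype=np.int64)
    chrom_np = np.array(chrom_arr)

    # --- Balding-Nichols frequencies --------------------------------------
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    F = cfg.fst_target
    if F > 0:
        scale = (1.0 - F) / F
        pop_freqs = rng.beta(
            np.tile((p_anc * scale)[:, None], (1, n_pops)),
            np.tile(((1.0 - p_anc) * scale)[:, None], (1, n_pops)),
        )
    else:
        pop_freqs = np.tile(p_anc[:, None], (1, n_pops))
    for chrom, pos, freqs in cfg.outlier_plants:
        i = int(np.flatnonzero((chrom_np == chrom) & (pos_arr == pos))[0])
        pop_freqs[i] = np.asarray(freqs, dtype=float)

    # --- background genotypes ---------------------------------------------
    calls = rng.binomial(2, pop_freqs[:, pop_col]).astype(np.int8)

    # --- planted strong-LD blocks from founder haplotype pools ------------
    for chrom, start, end, n_founders in cfg.block_plants:
        mask = (chrom_np == chrom) & (pos_arr >= start) & (pos_arr <= end)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        founders = rng.binomial(1, p_anc[idx][:, None], size=(idx.size, n_founders))
        # every planted-block SNP must segregate in the founder pool, else it
        # is monomorphic in the cohort and invisible to block detection
        mono = np.flatnonzero(founders.min(axis=1) == founders.max(axis=1))
        flip = rng.integers(0, n_founders, size=mono.size)
        founders[mono, flip] = 1 - founders[mono, flip]
        picks = rng.integers(0, n_founders, size=(2, n_total))
        calls[np.ix_(idx, np.arange(n_total))] = (
            founders[:, picks[0]] + founders[:, picks[1]]
        ).astype(np.int8)

    # --- missingness (never inside planted ROH tracts) --------------------
    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.missing_rate
        calls[miss] = -1

    # --- planted autozygous tracts: one founder haplotype, doubled --------
    col_of = {s: j for j, s in enumerate(samples)}
    for sample, chrom, start, end in cfg.roh_plants:
        j = col_of[sample]
        mask = (chrom_np == chrom) & (pos_arr >= start) & (pos_arr <= end)
        idx = np.flatnonzero(mask)
        hap = rng.binomial(1, pop_freqs[idx, pop_col[j]])
        calls[idx, j] = (2 * hap).astype(np.int8)

    gm = GenotypeMatrix(variants=variants, samples=samples, calls=calls, pop_of=pop_of)
    truth = TruthTable(
        roh_plants=list(cfg.roh_plants),
        block_plants=list(cfg.block_plants),
        outlier_plants=list(cfg.outlier_plants),
        pop_names=tuple(pop_names),
        pop_freqs=pop_freqs,
    )
    return gm, truth


def write_cohort(gm: GenotypeMatrix, truth: TruthTable, outdir) -> dict[str, str]:
    """Emit VCF + pop-map TSV + truth JSON; returns the paths written."""
    import os

    from .gio import write_pop_map, write_vcf

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "pop_map": os.path.join(outdir, "pop_map.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_vcf(gm, paths["vcf"])
    write_pop_map(gm.pop_of, paths["pop_map"])
    truth.to_json(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# consequence and expression emulation
# ---------------------------------------------------------------------------

_AA = list("ARNDCQEGHILKMFPSTWYV")

#: consequence label -> impact class, VEP convention
CONSEQUENCE_IMPACT = {
    "stop_gained": Impact.HIGH,
    "missense_variant": Impact.MODERATE,
    "synonymous_variant": Impact.LOW,
    "intron_variant": Impact.MODIFIER,
}


def simulate_consequences(
    gm: GenotypeMatrix,
    genes: list[GeneSpan],
    proportions: dict[str, float] | None = None,
    seed: int = 0,
) -> list[ConsequenceRecord]:
    """Assign a consequence to every variant falling inside a gene span.

    ``proportions`` maps consequence labels (keys of CONSEQUENCE_IMPACT) to
    sampling probabilities (normalized); missense records get a synthesized
    "X/Y" amino-acid change.
    """
    rng = np.random.default_rng(seed)
    props = proportions or {
        "missense_variant": 0.15,
        "synonymous_variant": 0.25,
        "intron_variant": 0.60,
    }
    labels = list(props)
    weights = np.array([props[c] for c in labels], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("proportions must have positive mass")
    weights /= weights.sum()
    records = []
    for g in genes:
        for i, v in enumerate(gm.variants):
            if v.chrom != g.chrom or not (g.start <= v.pos <= g.end):
                continue
            label = labels[int(rng.choice(len(labels), p=weights))]
            aa = ""
            if label == "missense_variant":
                a, b = rng.choice(len(_AA), size=2, replace=False)
                aa = f"{_AA[a]}/{_AA[b]}"
            records.append(
                ConsequenceRecord(
                    variant=v, gene_name=g.gene_name, consequence=label,
                    impact=CONSEQUENCE_IMPACT[label], aa_change=aa,
                )
            )
    return records


def simulate_tpm(
    genes: list[str],
    tissues: list[str],
    target_corr: float | dict[str, float] | dict[str, np.ndarray],
    n_per_tissue: int = 30,
    seed: int = 0,
    log_mean: float = 3.0,
    log_sd: float = 1.0,
) -> TpmMatrix:
    """Per-tissue multivariate-lognormal TPM with a requested correlation.

    ``target_corr`` is a scalar (every off-diagonal pair in every tissue), a
    tissue -> scalar map, or a tissue -> full correlation-matrix map. Samples
    are drawn per tissue from a multivariate normal on log scale and
    exponentiated, so rank correlations match the target; Pearson on the TPM
    scale is mildly attenuated by the monotone transform.
    """
    rng = np.random.default_rng(seed)
    k = len(genes)
    cols: list[np.ndarray] = []
    sample_names: list[str] = []
    tissue_of: dict[str, str] = {}
    for tissue in tissues:
        if isinstance(target_corr, dict):
            spec = target_corr[tissue]
        else:
            spec = target_corr
        if np.isscalar(spec):
            corr = np.full((k, k), float(spec))
            np.fill_diagonal(corr, 1.0)
        else:
            corr = np.asarray(spec, dtype=float)
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"target correlation for tissue {tissue!r} is not positive definite"
            ) from exc
        z = rng.standard_normal((n_per_tissue, k)) @ chol.T
        expr = np.exp(log_mean + log_sd * z)
        for i in range(n_per_tissue):
            name = f"{tissue}_{i + 1:03d}"
            sample_names.append(name)
            tissue_of[name] = tissue
            cols.append(expr[i])
    return TpmMatrix(
        genes=list(genes),
        samples=sample_names,
        tissue_of=tissue_of,
        tpm=np.column_stack(cols),
    )
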