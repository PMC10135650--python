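"""Data model and I/O for genotypes, population maps, annotations, and expression.

Genotypes are held as an ALT-allele dosage matrix (variants x samples) with
values 0/1/2 and -1 for missing; phase is ignored throughout the package.
Coordinates are 1-based inclusive everywhere; the length of a segment
[start, end] is ``end - start + 1``.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

#: Sus scrofa autosomes; QC drops anything outside this set by default.
PIG_AUTOSOMES = frozenset(str(c) for c in range(1, 19))


class FormatError(ValueError):
    """Malformed input file (missing GT field, bad table shape, ...)."""


class ConfigError(ValueError):
    """Inconsistent configuration (sample without population label, ...)."""


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP on a 1-based coordinate system."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotype calls with population labels.

    Attributes
    ----------
    variants : list of Variant, sorted by (chrom, pos), unique positions
    samples : sample identifiers, order fixed
    calls : int8 array (n_variants, n_samples); ALT dosage 0/1/2, -1 missing
    pop_of : sample id -> population label
    """

    variants: list[Variant]
    samples: list[str]
    calls: np.ndarray
    pop_of: dict[str, str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.variants)}, {len(self.samples)})"
            )
        seen: set[tuple[str, int]] = set()
        prev: tuple[str, int] | None = None
        for v in self.variants:
            key = (v.chrom, v.pos)
            if key in seen:
                raise ValueError(f"duplicate variant position {key}")
            seen.add(key)
            if prev is not None and prev[0] == v.chrom and prev[1] >= v.pos:
                raise ValueError(f"variants not sorted by position at {key}")
            prev = key
        missing_pops = [s for s in self.samples if s not in self.pop_of]
        if missing_pops:
            raise ConfigError(f"samples without population label: {missing_pops[:5]}")

    # -- convenience views -------------------------------------------------

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def chrom(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    @property
    def pos(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def populations(self) -> list[str]:
        """Distinct population labels, in first-appearance order over samples."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.pop_of[s], None)
        return list(seen)

    def sample_idx(self, pop: str) -> np.ndarray:
        """Column indices of the samples belonging to ``pop``."""
        idx = np.array(
            [i for i, s in enumerate(self.samples) if self.pop_of[s] == pop],
            dtype=np.intp,
        )
        if idx.size == 0:
            raise KeyError(f"unknown population {pop!r}")
        return idx

    def chrom_slices(self) -> dict[str, slice]:
        """Row-slice per chromosome (rows are chromosome-contiguous by sorting)."""
        out: dict[str, slice] = {}
        chroms = self.chrom
        start = 0
        for i in range(1, self.n_variants + 1):
            if i == self.n_variants or chroms[i] != chroms[start]:
                out[str(chroms[start])] = slice(start, i)
                start = i
        return out

    def subset(
        self,
        variant_idx: np.ndarray | Sequence[int] | None = None,
        sample_idx: np.ndarray | Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        samples = [self.samples[i] for i in si]
        return GenotypeMatrix(
            variants=[self.variants[i] for i in vi],
            samples=samples,
            calls=self.calls[np.ix_(vi, si)].copy(),
            pop_of={s: self.pop_of[s] for s in samples},
        )


@dataclass(frozen=True)
class GeneSpan:
    """Gene footprint on the genome, 1-based inclusive."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end for {self.gene_name}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


class Impact(IntEnum):
    """VEP-style impact levels, ordered for >= filtering."""

    MODIFIER = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3


@dataclass(frozen=True)
class ConsequenceRecord:
    """One predicted variant consequence (VEP-style table row)."""

    variant: Variant
    gene_name: str
    consequence: str
    impact: Impact
    aa_change: str = ""


@dataclass
class TpmMatrix:
    """Gene x sample TPM expression with a tissue label per sample."""

    genes: list[str]
    samples: list[str]
    tissue_of: dict[str, str]
    tpm: np.ndarray

    def __post_init__(self) -> None:
        self.tpm = np.asarray(self.tpm, dtype=float)
        if self.tpm.shape != (len(self.genes), len(self.samples)):
            raise ValueError("tpm shape mismatch")
        if np.any(self.tpm < 0):
            raise ValueError("TPM values must be nonnegative")
        unlabeled = [s for s in self.samples if s not in self.tissue_of]
        if unlabeled:
            raise ConfigError(f"samples without tissue label: {unlabeled[:5]}")

    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.tissue_of[s], None)
        return list(seen)

    def gene_row(self, gene: str) -> np.ndarray:
        return self.tpm[self.genes.index(gene)]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_pop_map(path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, population), header optional."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "sample_id" in cols and "population" in cols:
        df.columns = cols
    else:  # headerless
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, names=["sample_id", "population"])
    return dict(zip(df["sample_id"], df["population"]))


def read_vcf(path, pop_map_path) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix`.

    Non-biallelic records and non-SNP records (indels, symbolic alleles) are
    skipped with a logged count. Genotypes are coded as ALT dosage; any call
    with a missing allele is coded missing.

    Raises
    ------
    FormatError
        if the VCF carries no GT field.
    ConfigError
        if a VCF sample is absent from the population map.
    """
    from cyvcf2 import VCF

    pop_of = read_pop_map(pop_map_path)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in pop_of]
    if absent:
        raise ConfigError(f"VCF samples absent from population map: {absent[:5]}")

    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    saw_gt = False
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        if rec.ALT[0] not in "ACGT" or rec.REF not in "ACGT":
            n_skipped += 1
            continue
        gts = rec.gt_types  # 0=hom ref, 1=het, 2=hom alt, 3=missing (gts012)
        if gts is None:
            raise FormatError("VCF record lacks GT field")
        saw_gt = True
        row = np.asarray(gts, dtype=np.int8)
        row[row == 3] = MISSING
        variants.append(
            Variant(chrom=str(rec.CHROM), pos=int(rec.POS), ref=rec.REF,
                    alt=rec.ALT[0], id=rec.ID)
        )
        rows.append(row)
    if variants and not saw_gt:
        raise FormatError("VCF has no GT field")
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)

    order = sorted(range(len(variants)), key=lambda i: (_chrom_key(variants[i].chrom), variants[i].pos))
    calls = (
        np.vstack([rows[i] for i in order])
        if rows
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        variants=[variants[i] for i in order],
        samples=samples,
        calls=calls,
        pop_of={s: pop_of[s] for s in samples},
    )
    gm.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return gm


def _chrom_key(chrom: str) -> tuple[int, str]:
    return (int(chrom), "") if chrom.isdigit() else (10**9, chrom)


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the matrix as minimal VCF 4.2 (unphased GT only; gzip by suffix)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(v.chrom for v in gm.variants):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for i, v in enumerate(gm.variants):
            gts = "\t".join(_GT_CODE[int(c)] for c in gm.calls[i])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")


def write_pop_map(pop_of: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for s, p in pop_of.items():
            fh.write(f"{s}\t{p}\n")


def read_gene_spans(path) -> list[GeneSpan]:
    """Read gene spans from GFF3 (``gene`` features) or a 4/5-column TSV.

    TSV columns: gene_name, chrom, start, end (optionally gene_id first).
    Records with start > end are rejected with a warning.
    """
    path = str(path)
    spans: list[GeneSpan] = []
    with (gzip.open(path, "rt") if path.endswith(".gz") else open(path)) as fh:
        first = fh.readline()
        fh.seek(0)
        if first.startswith("##gff") or _looks_gff3(first):
            spans = _read_gff3_genes(fh)
        else:
            spans = _read_span_tsv(fh)
    return spans


def _looks_gff3(line: str) -> bool:
    parts = line.rstrip("\n").split("\t")
    return len(parts) == 9 and parts[6] in "+-.?"


def _read_gff3_genes(fh) -> list[GeneSpan]:
    spans = []
    for line in fh:
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 9 or parts[2].lower() != "gene":
            continue
        chrom, start, end = parts[0], int(parts[3]), int(parts[4])
        attrs = dict(
            kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
        )
        gene_id = attrs.get("ID", attrs.get("gene_id", ""))
        name = attrs.get("Name", attrs.get("gene_name", gene_id))
        if start > end:
            log.warning("rejecting gene %s: start > end", name)
            continue
        spans.append(GeneSpan(gene_id=gene_id, gene_name=name, chrom=chrom, start=start, end=end))
    return spans


def _read_span_tsv(fh) -> list[GeneSpan]:
    spans = []
    for ln, line in enumerate(fh):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if ln == 0 and not parts[-1].replace(",", "").isdigit():
            continue  # header row
        if len(parts) == 4:
            name, chrom, start, end = parts
            gene_id = name
        elif len(parts) >= 5:
            gene_id, name, chrom, start, end = parts[:5]
        else:
            raise FormatError(f"bad gene-span row: {line!r}")
        start_i, end_i = int(start.replace(",", "")), int(end.replace(",", ""))
        if start_i > end_i:
            log.warning("rejecting gene %s: start > end", name)
            continue
        spans.append(GeneSpan(gene_id=gene_id, gene_name=name, chrom=chrom, start=start_i, end=end_i))
    return spans


_IMPACT_NAMES = {i.name: i for i in Impact}


def read_consequences(path) -> list[ConsequenceRecord]:
    """Read a VEP-style consequence TSV.

    Columns: chrom, pos, ref, alt, gene, consequence, impact, aa_change.
    Rows with an unknown impact string are rejected with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for row in df.itertuples(index=False):
        impact = _IMPACT_NAMES.get(str(row.impact).upper())
        if impact is None:
            log.warning("rejecting consequence row with unknown impact %r", row.impact)
            continue
        records.append(
            ConsequenceRecord(
                variant=Variant(chrom=str(row.chrom), pos=int(row.pos), ref=row.ref, alt=row.alt),
                gene_name=row.gene,
                consequence=row.consequence,
                impact=impact,
                aa_change=getattr(row, "aa_change", "") or "",
            )
        )
    return records


def write_consequences(records: Iterable[ConsequenceRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\tconsequence\timpact\taa_change\n")
        for r in records:
            v = r.variant
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{r.gene_name}\t"
                     f"{r.consequence}\t{r.impact.name}\t{r.aa_change}\n")


def read_tpm(path, sample_meta_path) -> TpmMatrix:
    """Read a gene x sample TPM TSV plus a sample->tissue metadata TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(sample_meta_path, sep="\t", dtype=str)
    cols = [c.lower() for c in meta.columns]
    meta.columns = cols
    tissue_of = dict(zip(meta["sample_id"], meta["tissue"]))
    return TpmMatrix(
        genes=list(df.index),
        samples=list(df.columns),
        tissue_of=tissue_of,
        tpm=df.to_numpy(dtype=float),
    )


def write_tpm(tpm: TpmMatrix, path, sample_meta_path) -> None:
    pd.DataFrame(tpm.tpm, index=tpm.genes, columns=tpm.samples).to_csv(path, sep="\t")
    with open(sample_meta_path, "w") as fh:
        fh.write("sample_id\ttissue\n")
        for s in tpm.samples:
            fh.write(f"{s}\t{tpm.tissue_of[s]}\n")


# ---------------------------------------------------------------------------
# allele counting
# ---------------------------------------------------------------------------


def allele_counts(gm: GenotypeMatrix, pop: str, variant_idx: int) -> tuple[int, int]:
    """REF/ALT allele counts for one population at one variant.

    ``ref + alt`` equals twice the number of non-missing diploid samples of
    the population at the site.
    """
    cols = gm.sample_idx(pop)
    calls = gm.calls[variant_idx, cols]
    ok = calls != MISSING
    alt = int(calls[ok].sum())
    ref = int(2 * ok.sum() - alt)
    return ref, alt


def allele_count_matrix(gm: GenotypeMatrix, pop: str) -> np.ndarray:
    """(n_variants, 2) array of REF/ALT counts for ``pop`` (vectorized)."""
    cols = gm.sample_idx(pop)
    calls = gm.calls[:, cols]
    ok = calls != MISSING
    alt = np.where(ok, calls, 0).sum(axis=1)
    ref = 2 * ok.sum(axis=1) - alt
    return np.stack([ref, alt], axis=1)
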