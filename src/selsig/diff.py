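"""Allele-differentiation tests and candidate-gene follow-up.

Per-locus 2x2 Fisher exact tests contrast REF/ALT allele counts between the
focal breed and a comparison group; per-gene summaries report the fraction
of significant loci; consequence records are filtered to moderate-or-higher
impact; candidate-gene co-expression is checked by per-tissue Pearson
correlation of TPM values. All p-values are raw (no multiple-testing
correction) — the screen is deliberately permissive and downstream evidence
is what narrows it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gio import (
    ConsequenceRecord,
    GeneSpan,
    GenotypeMatrix,
    Impact,
    TpmMatrix,
    allele_count_matrix,
)

log = logging.getLogger(__name__)

_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = populations, columns = (REF, ALT) allele counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")


def fisher_exact_2x2(table: ContingencyTable2x2 | tuple | list) -> float:
    """Two-sided Fisher exact p by direct hypergeometric enumeration.

    Sums P(table) over every table with the observed margins whose
    hypergeometric probability is <= the observed one (minimum-likelihood
    convention), with a 1e-12 relative tolerance for probability ties.
    A table with an empty margin returns p = 1 by convention.
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    if row1 == 0 or row2 == 0 or col1 == 0 or col1 == n:
        log.debug("fisher_exact_2x2: empty margin, p = 1 by convention")
        return 1.0
    rv = stats.hypergeom(n, col1, row1)
    support = np.arange(max(0, col1 - row2), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum()))


def significance_stars(p: float) -> str:
    """Star notation: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class LocusTestResult:
    chrom: str
    pos: int
    gene_name: str
    pair: tuple[str, str]
    table: ContingencyTable2x2
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def test_gene_loci(
    gm: GenotypeMatrix, gene_span: GeneSpan, popA: str, popB: str
) -> list[LocusTestResult]:
    """Fisher test at every variant inside the gene span."""
    countsA = allele_count_matrix(gm, popA)
    countsB = allele_count_matrix(gm, popB)
    results = []
    for i, v in enumerate(gm.variants):
        if v.chrom != gene_span.chrom or not (gene_span.start <= v.pos <= gene_span.end):
            continue
        table = ContingencyTable2x2(
            int(countsA[i, 0]), int(countsA[i, 1]),
            int(countsB[i, 0]), int(countsB[i, 1]),
        )
        results.append(
            LocusTestResult(
                chrom=v.chrom, pos=v.pos, gene_name=gene_span.gene_name,
                pair=(popA, popB), table=table, p_value=fisher_exact_2x2(table),
            )
        )
    if not results:
        log.warning("no variants inside span of gene %s", gene_span.gene_name)
    return results


@dataclass(frozen=True)
class GeneDiffSummary:
    gene_name: str
    n_loci: int
    n_sig_pair1: int
    n_sig_pair2: int

    @property
    def prop_sig_pair1(self) -> float:
        return self.n_sig_pair1 / self.n_loci

    @property
    def prop_sig_pair2(self) -> float:
        return self.n_sig_pair2 / self.n_loci


def gene_diff_summary(
    results_pair1: list[LocusTestResult], results_pair2: list[LocusTestResult]
) -> dict[str, GeneDiffSummary]:
    """Per-gene significant-locus proportions for the two comparisons.

    The locus universe per gene is the union of loci tested in either pair
    (normally identical). Genes with zero tested loci are skipped.
    """
    loci: dict[str, set[tuple[str, int]]] = {}
    sig1: dict[str, int] = {}
    sig2: dict[str, int] = {}
    for res, sig in ((results_pair1, sig1), (results_pair2, sig2)):
        for r in res:
            loci.setdefault(r.gene_name, set()).add((r.chrom, r.pos))
            if r.significant:
                sig[r.gene_name] = sig.get(r.gene_name, 0) + 1
    out = {}
    for gene, ll in loci.items():
        if not ll:
            continue
        out[gene] = GeneDiffSummary(
            gene_name=gene,
            n_loci=len(ll),
            n_sig_pair1=sig1.get(gene, 0),
            n_sig_pair2=sig2.get(gene, 0),
        )
    return out


def impact_filter(
    records: list[ConsequenceRecord], min_impact: Impact = Impact.MODERATE
) -> tuple[list[ConsequenceRecord], dict[str, int]]:
    """Keep records with impact >= min_impact; also return per-gene counts."""
    kept = [r for r in records if r.impact >= min_impact]
    per_gene: dict[str, int] = {}
    for r in kept:
        per_gene[r.gene_name] = per_gene.get(r.gene_name, 0) + 1
    return kept, per_gene


@dataclass(frozen=True)
class TissueCorrelation:
    gene_a: str
    gene_b: str
    tissue: str
    r: float
    p_value: float
    n_samples: int


def expression_correlation(
    tpm: TpmMatrix,
    gene_pairs: list[tuple[str, str]],
    alpha: float = 0.05,
) -> list[TissueCorrelation]:
    """Per-tissue Pearson correlations of TPM for each gene pair.

    Only results with p < alpha are returned; tissues with fewer than 3
    samples, or a zero-variance gene within a tissue, are dropped with a
    warning. The p-value is the two-sided t-transform with n-2 df.
    """
    cols_of: dict[str, list[int]] = {}
    for j, s in enumerate(tpm.samples):
        cols_of.setdefault(tpm.tissue_of[s], []).append(j)
    out = []
    for ga, gb in gene_pairs:
        xa, xb = tpm.gene_row(ga), tpm.gene_row(gb)
        for tissue, cols in cols_of.items():
            if len(cols) < 3:
                log.warning("tissue %s has < 3 samples; skipped", tissue)
                continue
            x, y = xa[cols], xb[cols]
            if np.std(x) == 0 or np.std(y) == 0:
                log.warning("zero-variance gene in tissue %s for (%s, %s); dropped",
                            tissue, ga, gb)
                continue
            res = stats.pearsonr(x, y)
            if res.pvalue < alpha:
                out.append(
                    TissueCorrelation(ga, gb, tissue, float(res.statistic),
                                      float(res.pvalue), len(cols))
                )
    return out


def write_locus_tests_tsv(results: list[LocusTestResult], path) -> None:
    """TSV mirroring the per-locus allele table: counts, p, stars."""
    with open(path, "w") as fh:
        fh.write("gene\tsnp\tpopA_ref\tpopA_alt\tpopB_ref\tpopB_alt\tp_value\tstars\n")
        for r in results:
            t = r.table
            fh.write(f"{r.gene_name}\t{r.chrom}:{r.pos}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t"
                     f"{r.p_value:.3e}\t{significance_stars(r.p_value)}\n")


def write_correlations_tsv(corrs: list[TissueCorrelation], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\ttissue\tr\tp_value\tn\n")
        for c in corrs:
            fh.write(f"{c.gene_a}\t{c.gene_b}\t{c.tissue}\t{c.r:.4f}\t"
                     f"{c.p_value:.3e}\t{c.n_samples}\n")
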