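"""Evidence integration: regions -> genes -> multi-method intersection.

Four evidence sources feed the final candidate set: ROH islands, top
haplotype blocks, and two F_ST scans (focal vs other-indigenous, focal vs
commercial). A gene is a candidate when at least ``min_sources`` of the
four sources hit its span (closed-interval overlap, same 1-based inclusive
coordinates on both sides).
"""

from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from enum import Enum

from .gio import GeneSpan

log = logging.getLogger(__name__)


class EvidenceSource(str, Enum):
    ROH_ISLAND = "ROH_ISLAND"
    HAPLO_BLOCK = "HAPLO_BLOCK"
    FST_1 = "FST_1"  # focal vs other indigenous breeds
    FST_2 = "FST_2"  # focal vs commercial breeds


@dataclass(frozen=True)
class CandidateRegion:
    source: EvidenceSource
    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("region start > end")


@dataclass
class EvidenceLedger:
    """gene_name -> set of evidence sources that detected it."""

    sources_of: dict[str, set[EvidenceSource]]

    def genes(self) -> list[str]:
        return sorted(self.sources_of)


def snps_to_regions(
    selected: list[tuple[str, int]],
    source: EvidenceSource,
    flank_bp: int = 0,
) -> list[CandidateRegion]:
    """Turn selected SNPs into (merged) candidate regions.

    Each SNP (chrom, pos) becomes [pos - flank, pos + flank] clipped at 1;
    overlapping or touching regions from the same source are merged.
    """
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for chrom, pos in selected:
        by_chrom[chrom].append(pos)
    regions: list[CandidateRegion] = []
    for chrom, positions in by_chrom.items():
        positions.sort()
        start = end = None
        for p in positions:
            lo, hi = max(1, p - flank_bp), p + flank_bp
            if start is None:
                start, end = lo, hi
            elif lo <= end + 1:  # overlap or adjacency merges
                end = max(end, hi)
            else:
                regions.append(CandidateRegion(source, chrom, start, end))
                start, end = lo, hi
        if start is not None:
            regions.append(CandidateRegion(source, chrom, start, end))
    regions.sort(key=lambda r: (r.chrom, r.start_bp))
    return regions


def intervals_to_regions(
    intervals: list[tuple[str, int, int]], source: EvidenceSource
) -> list[CandidateRegion]:
    """Wrap already-interval-shaped evidence (islands, blocks) as regions."""
    return [
        CandidateRegion(source, chrom, start, end)
        for chrom, start, end in intervals
    ]


def regions_to_genes(
    regions: list[CandidateRegion], gene_spans: list[GeneSpan]
) -> EvidenceLedger:
    """Record each gene under every source with an overlapping region."""
    genes_by_chrom: dict[str, list[GeneSpan]] = defaultdict(list)
    for g in gene_spans:
        genes_by_chrom[g.chrom].append(g)
    region_chroms = {r.chrom for r in regions}
    orphan = region_chroms - set(genes_by_chrom)
    if orphan:
        log.warning("regions on chromosomes with no annotated genes: %s", sorted(orphan))

    ledger: dict[str, set[EvidenceSource]] = defaultdict(set)
    for r in regions:
        for g in genes_by_chrom.get(r.chrom, []):
            if g.start <= r.end_bp and r.start_bp <= g.end:  # closed-interval overlap
                ledger[g.gene_name].add(r.source)
    return EvidenceLedger(sources_of=dict(ledger))


def intersect_evidence(
    ledger: EvidenceLedger, min_sources: int = 2
) -> tuple[list[str], dict[str, int]]:
    """Candidate genes hit by >= min_sources methods, plus Venn counts.

    The Venn table maps each observed source combination (sorted,
    '+'-joined) to its gene count; counts sum to the ledger's gene total.
    """
    candidates = sorted(
        g for g, srcs in ledger.sources_of.items() if len(srcs) >= min_sources
    )
    venn = Counter(
        "+".join(sorted(s.value for s in srcs))
        for srcs in ledger.sources_of.values()
    )
    return candidates, dict(sorted(venn.items()))


def write_ledger_tsv(ledger: EvidenceLedger, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tsources\tn_sources\n")
        for g in ledger.genes():
            srcs = sorted(s.value for s in ledger.sources_of[g])
            fh.write(f"{g}\t{','.join(srcs)}\t{len(srcs)}\n")


def write_venn_json(venn: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        json.dump(venn, fh, indent=2)
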