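"""End-to-end orchestration: QC -> ROH -> blocks -> F_ST x2 -> integration -> tests.

Every stage writes its table under the output directory and appends a row
count to the run manifest; stage outputs are pure functions of
(inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from itertools import combinations

from . import __version__
from .gio import (
    GenotypeMatrix,
    read_consequences,
    read_gene_spans,
    read_tpm,
    read_vcf,
)
from .qc import QcConfig, filter_genotypes
from .roh import RohConfig, call_islands, classify_roh, detect_roh_all, roh_incidence, \
    write_islands_tsv, write_segments_tsv
from .ldblocks import BlockConfig, find_blocks, top_blocks, write_blocks_tsv
from .fst import top_snps, wc_fst, write_fst_tsv
from .integrate import (
    EvidenceSource,
    intersect_evidence,
    intervals_to_regions,
    regions_to_genes,
    snps_to_regions,
    write_ledger_tsv,
    write_venn_json,
)
from .diff import (
    expression_correlation,
    gene_diff_summary,
    impact_filter,
    test_gene_loci,
    write_correlations_tsv,
    write_locus_tests_tsv,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str
    pop_map: str
    gene_spans: str
    outdir: str
    focal_pop: str
    pair1_pops: list[str]  # other-indigenous comparison set
    pair2_pops: list[str]  # commercial comparison set
    consequences: str | None = None
    tpm: str | None = None
    tpm_meta: str | None = None
    seed: int = 0
    top_fraction: float = 0.01
    qc: QcConfig = field(default_factory=QcConfig)
    roh: RohConfig = field(default_factory=RohConfig)
    blocks: BlockConfig = field(default_factory=BlockConfig)

    def __post_init__(self) -> None:
        overlap = set(self.pair1_pops + self.pair2_pops) & {self.focal_pop}
        if overlap:
            raise ValueError("focal_pop must be disjoint from comparison sets")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _merged_pop_view(gm: GenotypeMatrix, groups: dict[str, list[str]]) -> GenotypeMatrix:
    """Relabel populations so each listed group becomes one pooled label."""
    label_of = {}
    for merged, members in groups.items():
        for m in members:
            label_of[m] = merged
    pop_of = {s: label_of.get(p, p) for s, p in gm.pop_of.items()}
    return GenotypeMatrix(gm.variants, gm.samples, gm.calls, pop_of)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to JSON)."""
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(repr(cfg).encode()).hexdigest()[:16],
        "stages": {},
    }

    def _stage(name):
        def deco(fn):
            try:
                counts = fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage name
                raise StageError(name, exc) from exc
            manifest["stages"][name] = counts
            log.info("stage %s: %s", name, counts)

        return deco

    state: dict = {}

    @_stage("qc")
    def _qc():
        gm = read_vcf(cfg.vcf, cfg.pop_map)
        filtered, rep = filter_genotypes(gm, cfg.qc)
        rep.to_json(os.path.join(cfg.outdir, "qc_report.json"))
        state["gm"] = filtered
        return {"variants_in": gm.n_variants, "variants_out": filtered.n_variants,
                "samples_out": filtered.n_samples}

    @_stage("roh")
    def _roh():
        gm = state["gm"]
        focal_cols = gm.sample_idx(cfg.focal_pop)
        focal = gm.subset(sample_idx=focal_cols)
        segments = detect_roh_all(focal, cfg.roh)
        write_segments_tsv(segments, os.path.join(cfg.outdir, "roh_segments.tsv"))
        classes = classify_roh(segments)
        with open(os.path.join(cfg.outdir, "roh_classes.json"), "w") as fh:
            json.dump(classes, fh, indent=2)
        incidence = roh_incidence(segments, focal)
        islands = call_islands(incidence, focal, cfg.top_fraction)
        write_islands_tsv(islands, os.path.join(cfg.outdir, "roh_islands.tsv"),
                          bed_path=os.path.join(cfg.outdir, "roh_islands.bed"))
        state["islands"] = islands
        return {"segments": len(segments), "islands": len(islands)}

    @_stage("blocks")
    def _blocks():
        gm = state["gm"]
        focal = gm.subset(sample_idx=gm.sample_idx(cfg.focal_pop))
        blocks = find_blocks(focal, cfg.blocks)
        write_blocks_tsv(blocks, os.path.join(cfg.outdir, "haplo_blocks.tsv"))
        top = top_blocks(blocks, cfg.top_fraction)
        write_blocks_tsv(top, os.path.join(cfg.outdir, "haplo_blocks_top.tsv"))
        state["top_blocks"] = top
        return {"blocks": len(blocks), "top_blocks": len(top)}

    @_stage("fst")
    def _fst():
        gm = state["gm"]
        counts = {}
        for tag, members in (("fst1", cfg.pair1_pops), ("fst2", cfg.pair2_pops)):
            view = _merged_pop_view(gm, {tag: members})
            records = wc_fst(view, cfg.focal_pop, tag)
            write_fst_tsv(records, os.path.join(cfg.outdir, f"{tag}_per_snp.tsv"))
            scan = top_snps(records, cfg.top_fraction)
            state[tag] = scan
            counts[tag] = {"defined": sum(r.theta is not None for r in records),
                           "selected": len(scan.selected),
                           "threshold": scan.threshold}
        return counts

    @_stage("integrate")
    def _integrate():
        regions = []
        regions += intervals_to_regions(
            [(i.chrom, i.start_bp, i.end_bp) for i in state["islands"]],
            EvidenceSource.ROH_ISLAND,
        )
        regions += intervals_to_regions(
            [(b.chrom, b.start_bp, b.end_bp) for b in state["top_blocks"]],
            EvidenceSource.HAPLO_BLOCK,
        )
        for tag, src in (("fst1", EvidenceSource.FST_1), ("fst2", EvidenceSource.FST_2)):
            scan = state[tag]
            snps = [(scan.records[i].variant.chrom, scan.records[i].variant.pos)
                    for i in scan.selected]
            regions += snps_to_regions(snps, src)
        spans = read_gene_spans(cfg.gene_spans)
        state["spans"] = spans
        ledger = regions_to_genes(regions, spans)
        candidates, venn = intersect_evidence(ledger, min_sources=2)
        write_ledger_tsv(ledger, os.path.join(cfg.outdir, "evidence_ledger.tsv"))
        write_venn_json(venn, os.path.join(cfg.outdir, "venn_counts.json"))
        with open(os.path.join(cfg.outdir, "candidate_genes.tsv"), "w") as fh:
            fh.write("gene\n" + "".join(g + "\n" for g in candidates))
        state["candidates"] = candidates
        return {"regions": len(regions), "genes_in_ledger": len(ledger.sources_of),
                "candidates": len(candidates)}

    @_stage("diff")
    def _diff():
        gm = state["gm"]
        span_of = {s.gene_name: s for s in state["spans"]}
        res1, res2 = [], []
        for tag, members, bucket in (("fst1", cfg.pair1_pops, res1),
                                     ("fst2", cfg.pair2_pops, res2)):
            view = _merged_pop_view(gm, {tag: members})
            for gene in state["candidates"]:
                if gene in span_of:
                    bucket.extend(test_gene_loci(view, span_of[gene], cfg.focal_pop, tag))
        write_locus_tests_tsv(res1 + res2, os.path.join(cfg.outdir, "locus_tests.tsv"))
        summaries = gene_diff_summary(res1, res2)
        with open(os.path.join(cfg.outdir, "gene_diff_summary.tsv"), "w") as fh:
            fh.write("gene\tn_loci\tn_sig_pair1\tn_sig_pair2\tprop_sig_pair1\tprop_sig_pair2\n")
            for s in summaries.values():
                fh.write(f"{s.gene_name}\t{s.n_loci}\t{s.n_sig_pair1}\t{s.n_sig_pair2}\t"
                         f"{s.prop_sig_pair1:.4f}\t{s.prop_sig_pair2:.4f}\n")
        counts = {"loci_tested": len(res1) + len(res2)}
        if cfg.consequences:
            records = read_consequences(cfg.consequences)
            kept, per_gene = impact_filter(records)
            with open(os.path.join(cfg.outdir, "impact_counts.json"), "w") as fh:
                json.dump(per_gene, fh, indent=2)
            counts["impact_kept"] = len(kept)
        return counts

    @_stage("expression")
    def _expression():
        if not (cfg.tpm and cfg.tpm_meta):
            log.info("expression stage skipped: no TPM input configured")
            return {"skipped": True}
        tpm = read_tpm(cfg.tpm, cfg.tpm_meta)
        genes = [g for g in state["candidates"] if g in tpm.genes]
        pairs = list(combinations(genes, 2))
        corrs = expression_correlation(tpm, pairs)
        write_correlations_tsv(corrs, os.path.join(cfg.outdir, "expression_correlations.tsv"))
        return {"pairs_tested": len(pairs), "retained": len(corrs)}

    manifest["n_stages"] = len(manifest["stages"])
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
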