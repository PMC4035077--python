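"""Orchestration: simulate/ingest -> demux -> QC -> reference -> SNPs ->
genotypes -> linkage map, with persisted artifacts and a summary report.

All randomness flows from the single config seed (only the simulator
draws random numbers); a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from pathlib import Path

import numpy as np

from . import io as dio
from .config import PipelineConfig
from .demux import (SampleSheet, demultiplex, quality_filter,
                    read_fastq_pairs, write_demux_report)
from .enzymes import EnzymeSpec
from .linkage import build_map, map_statistics
from .reference import align_to_tags, build_consensus, cluster_reads
from .simulate import SimConfig, simulate_dataset
from .variants import (GEN_H, GEN_MISSING, allele_counts_for_sample,
                       build_genotype_matrix, call_genotypes_array,
                       call_parental_snps, drop_high_het_markers, f9_prior,
                       pileup_counts, reduce_reference)

log = logging.getLogger("ddradmap")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sim_config(cfg: PipelineConfig) -> SimConfig:
    kwargs = dict(cfg.sim)
    kwargs.setdefault("seed", cfg.seed)
    for key in ("enzyme_a", "enzyme_b"):
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = EnzymeSpec(**kwargs[key])
    if "barcode_set" in kwargs:
        kwargs["barcode_set"] = tuple(kwargs["barcode_set"])
    if "insert_window" in kwargs:
        kwargs["insert_window"] = tuple(kwargs["insert_window"])
    return SimConfig(**kwargs)


def run_pipeline(cfg: PipelineConfig):
    """Execute all stages; returns (summary dict, artifacts dict).

    Artifacts are written under ``cfg.outdir``; any stage failure raises
    :class:`StageError` naming the stage, leaving partial artifacts in
    place.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_seed": cfg.seed, "mode": cfg.mode, "stages": {}}
    artifacts: dict = {}
    truth = None

    # ---------------------------------------------------------- simulate
    if cfg.mode == "simulate":
        log.info("stage simulate: generating synthetic cross and reads")
        try:
            sim_cfg = _sim_config(cfg)
            truth, manifest = simulate_dataset(sim_cfg, outdir / "sim")
        except Exception as exc:
            raise StageError("simulate", str(exc)) from exc
        pools = list(manifest["pools"].values())
        sheet_path = manifest["sample_sheet"]
        summary["stages"]["simulate"] = {
            "n_tags": truth.n_tags,
            "n_true_snps": len(truth.true_snps),
            "n_individuals": sim_cfg.n_individuals,
            "pairs_written": int(sum(manifest["pair_counts"].values())),
        }
    else:
        pools = [tuple(p) for p in cfg.pools]
        sheet_path = cfg.sample_sheet

    # ------------------------------------------------------- demux + QC
    log.info("stage demux/qc: assigning pooled reads to individuals")
    try:
        sheet = SampleSheet.from_tsv(sheet_path)
    except Exception as exc:
        raise StageError("demux", f"cannot read sample sheet: {exc}") from exc
    # enzymes come from the sim section (defaults SacI/MseI) in both modes
    _enzymes = _sim_config(cfg)
    enz_a, enz_b = _enzymes.enzyme_a, _enzymes.enzyme_b

    sample_seqs: dict[str, list] = {r.sample: [] for r in sheet.rows}
    total_pairs = assigned_pairs = 0
    per_sample_pairs = Counter()
    raw_len_mode = Counter()
    qc_pairs_kept = 0
    q20_num = q20_den = 0
    pool_paths = {}
    for row in sheet.rows:
        pool_paths.setdefault(row.pool, None)
    if len(pools) != len(pool_paths):
        raise StageError("demux", f"sample sheet lists {len(pool_paths)} "
                         f"pools but {len(pools)} pool FASTQ pairs given")
    for pool_id, (p1, p2) in zip(sheet.pools, pools):
        rows = sheet.pool_rows(pool_id)
        try:
            pairs = list(read_fastq_pairs(p1, p2))
        except Exception as exc:
            raise StageError("demux", f"pool {pool_id}: {exc}") from exc
        for pr in pairs:
            raw_len_mode[len(pr.seq1)] += 1
        per_sample, stats = demultiplex(
            pairs, rows, enz_a, enz_b,
            trim_remnant=cfg.demux.trim_remnant,
            check_read2_remnant=cfg.demux.check_read2_remnant)
        total_pairs += stats.total_pairs
        assigned_pairs += stats.n_assigned
        per_sample_pairs.update(stats.assigned_pairs)
        for sample, sp in per_sample.items():
            kept, qstats = quality_filter(sp, cfg.qc.q_threshold,
                                          cfg.qc.min_length)
            qc_pairs_kept += len(kept)
            for pr in kept:
                sample_seqs[sample].append(pr.seq1)
                sample_seqs[sample].append(pr.seq2)
            n_bases = sum(len(p.qual1) + len(p.qual2) for p in kept)
            q20_den += n_bases
            q20_num += int(round(qstats["q20_ratio"] * n_bases)) \
                if n_bases else 0

    from .demux import DemuxStats
    report = DemuxStats(total_pairs=total_pairs,
                        assigned_pairs=dict(per_sample_pairs))
    write_demux_report(report, outdir / "demux_report.tsv")
    artifacts["demux_report"] = str(outdir / "demux_report.tsv")
    summary["stages"]["demux"] = {
        "pairs_in": total_pairs,
        "pairs_assigned": assigned_pairs,
        "pairs_unassigned": total_pairs - assigned_pairs,
    }
    summary["stages"]["qc"] = {
        "pairs_kept": qc_pairs_kept,
        "q20_ratio": (q20_num / q20_den) if q20_den else None,
    }

    # uniform working length: reads are anchored at the cut site, so all
    # information lives in the first L bases common to every sample
    if not raw_len_mode:
        raise StageError("qc", "no reads after demultiplexing")
    raw_read_len = raw_len_mode.most_common(1)[0][0]
    max_bc = max(len(r.barcode) for r in sheet.rows)
    cluster_len = raw_read_len - max_bc
    if cfg.demux.trim_remnant:
        cluster_len -= len(enz_a.remnant)

    n_short = 0
    for sample, seqs in sample_seqs.items():
        trimmed = []
        for s in seqs:
            if len(s) >= cluster_len:
                trimmed.append(s[:cluster_len])
            else:
                n_short += 1
        sample_seqs[sample] = trimmed
    summary["stages"]["qc"]["reads_below_cluster_length"] = n_short
    summary["stages"]["qc"]["cluster_length"] = cluster_len

    # ---------------------------------------------------------- reference
    log.info("stage reference: clustering parental reads")
    parent_samples = {r.role: r.sample for r in sheet.rows
                      if r.role in ("parent1", "parent2")}
    if set(parent_samples) != {"parent1", "parent2"}:
        raise StageError("reference",
                         "sample sheet must mark one parent1 and one parent2")
    p1, p2 = parent_samples["parent1"], parent_samples["parent2"]
    parent_reads = sample_seqs[p1] + sample_seqs[p2]
    if not parent_reads:
        raise StageError("reference", "no parental reads survive QC")
    clusters = cluster_reads(parent_reads,
                             radius=cfg.reference.cluster_radius,
                             min_cluster_depth=cfg.reference.min_cluster_depth)
    tags = build_consensus(clusters)
    if not tags:
        raise StageError("reference", "no clusters above minimum depth")
    dio.write_tags_fasta(tags, outdir / "tags.fasta")
    artifacts["tags_fasta"] = str(outdir / "tags.fasta")
    summary["stages"]["reference"] = {
        "n_parent_reads": len(parent_reads),
        "n_tags": len(tags),
    }

    # ------------------------------------------------------ parental SNPs
    log.info("stage variants: calling SNPs between the parents")
    piles = {}
    align_counts = {}
    for sample in (p1, p2):
        reads = list(enumerate(sample_seqs[sample]))
        res = align_to_tags(reads, tags,
                            max_mismatches=cfg.reference.max_mismatches,
                            repeat_hit_limit=cfg.reference.repeat_hit_limit)
        align_counts[sample] = dict(res.class_counts)
        piles[sample] = pileup_counts(res, sample_seqs[sample], len(tags),
                                      cluster_len)
    snps, reject_tally = call_parental_snps(
        piles[p1], piles[p2], tags,
        min_allele_depth=cfg.variants.min_allele_depth)
    summary["stages"]["parental_snps"] = {
        "alignment_classes": align_counts,
        "n_snps": len(snps),
        "rejected": reject_tally,
    }
    if not snps:
        raise StageError("variants",
                         "no parental SNPs pass the filters; cannot build "
                         "a reduced reference")

    reduced = reduce_reference(tags, snps)
    dio.write_tags_fasta(reduced, outdir / "reduced_tags.fasta")
    artifacts["reduced_tags_fasta"] = str(outdir / "reduced_tags.fasta")
    summary["stages"]["parental_snps"]["n_reduced_tags"] = len(reduced)

    # ------------------------------------------------------- RIL genotypes
    log.info("stage genotype: Bayesian calls for the RIL population")
    red_index = {t.id: i for i, t in enumerate(reduced)}
    from .reference import _CODE_LUT as _LUT  # base byte -> 0..3
    snp_tag_idx = np.array([red_index[s.tag_id] for s in snps],
                           dtype=np.int64)
    snp_pos = np.array([s.position for s in snps], dtype=np.int64)
    snp_a = np.array([_LUT[ord(s.allele_p1)] for s in snps], dtype=np.uint8)
    snp_b = np.array([_LUT[ord(s.allele_p2)] for s in snps], dtype=np.uint8)

    rils = [r.sample for r in sheet.rows if r.role == "ril"]
    n_snps = len(snps)
    counts_a = np.zeros((n_snps, len(rils)), dtype=np.int32)
    counts_b = np.zeros((n_snps, len(rils)), dtype=np.int32)
    third_flag = np.zeros(n_snps, dtype=bool)
    for k, sample in enumerate(rils):
        reads = list(enumerate(sample_seqs[sample]))
        res = align_to_tags(reads, reduced,
                            max_mismatches=cfg.reference.max_mismatches,
                            repeat_hit_limit=cfg.reference.repeat_hit_limit)
        ca, cb, cother = allele_counts_for_sample(
            res, sample_seqs[sample], snp_tag_idx, snp_pos, snp_a, snp_b,
            len(reduced))
        counts_a[:, k] = ca
        counts_b[:, k] = cb
        depth = ca + cb + cother
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(depth > 0, cother / np.maximum(depth, 1), 0.0)
        third_flag |= frac > cfg.variants.third_allele_fraction

    prior = (f9_prior(8) if cfg.variants.prior == "f9"
             else (1 / 3, 1 / 3, 1 / 3))
    codes, _post = call_genotypes_array(
        counts_a, counts_b, error_rate=cfg.variants.genotype_error_rate,
        prior=prior, min_allele_depth=cfg.variants.min_allele_depth,
        het_policy="keep")
    n_het_calls = int((codes == GEN_H).sum())
    if cfg.variants.het_policy == "mask":
        codes[codes == GEN_H] = GEN_MISSING

    if cfg.variants.het_policy == "strict":
        keep = drop_high_het_markers(codes,
                                     cfg.variants.het_locus_threshold)
        codes = codes[keep]
        snps = [s for s, k in zip(snps, keep) if k]
        third_flag = third_flag[keep]
    marker_ids = [f"{s.tag_id}:{s.position + 1}" for s in snps]
    matrix, filter_tally = build_genotype_matrix(
        codes, marker_ids, rils, snps=snps, mmd=cfg.variants.mmd,
        min_allele_individuals=cfg.variants.min_allele_individuals)
    summary["stages"]["genotype"] = {
        "markers_in": filter_tally["markers_in"],
        "markers_retained": filter_tally["retained"],
        "dropped_mmd": filter_tally["dropped_mmd"],
        "dropped_minor_allele": filter_tally["dropped_minor_allele"],
        "het_calls": n_het_calls,
        "missing_fraction": float((matrix.codes == GEN_MISSING).mean())
        if matrix.n_markers else None,
        "third_allele_flagged": int(third_flag.sum()),
    }
    if matrix.n_markers == 0:
        raise StageError("genotype", "no markers pass the presence filters")

    dio.write_genotype_tsv(matrix, outdir / "genotypes.tsv")
    dio.write_vcf(matrix, outdir / "genotypes.vcf")
    dio.write_loc(matrix, outdir / "genotypes.loc")
    dio.write_snp_flanks(matrix.snps, matrix.marker_ids,
                         outdir / "snp_flanks.tsv")
    artifacts.update(genotypes_tsv=str(outdir / "genotypes.tsv"),
                     vcf=str(outdir / "genotypes.vcf"),
                     loc=str(outdir / "genotypes.loc"),
                     snp_flanks=str(outdir / "snp_flanks.tsv"))

    # ------------------------------------------------------------ linkage
    log.info("stage linkage: grouping, ordering, map statistics")
    genetic_map = build_map(
        matrix, max_rf=cfg.linkage.max_rf, min_lod=cfg.linkage.min_lod,
        min_informative=cfg.linkage.min_informative,
        min_shared=cfg.linkage.min_shared, alpha=cfg.linkage.alpha,
        min_sdr_markers=cfg.linkage.min_sdr_markers)
    stats = map_statistics(genetic_map)
    dio.write_map_tsv(genetic_map, outdir / "map.tsv")
    dio.write_mapchart(genetic_map, outdir / "map_chart.txt")
    dio.write_statistics_tsv(stats, outdir / "map_statistics.tsv")
    artifacts.update(map_tsv=str(outdir / "map.tsv"),
                     mapchart=str(outdir / "map_chart.txt"),
                     statistics=str(outdir / "map_statistics.tsv"))
    summary["stages"]["linkage"] = {
        "n_groups": len(genetic_map.groups),
        "n_linked_markers": int(sum(len(g.marker_ids)
                                    for g in genetic_map.groups)),
        "n_unlinked_markers": len(genetic_map.unlinked_markers),
        "total_length_cM": float(genetic_map.total_length),
        "n_bins": int(sum(len(g.bins) for g in genetic_map.groups)),
        "n_distorted": int(sum(
            1 for g in genetic_map.groups
            for t in g.distortion if t.testable and t.distorted)),
        "n_sdrs": int(sum(len(g.sdrs) for g in genetic_map.groups)),
    }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    artifacts["summary"] = str(outdir / "summary.json")

    result = PipelineResult(summary=summary, artifacts=artifacts,
                            matrix=matrix, genetic_map=genetic_map,
                            tags=tags, reduced_tags=reduced, snps=list(snps),
                            truth=truth, statistics=stats)
    return result


@dataclasses.dataclass
class PipelineResult:
    summary: dict
    artifacts: dict
    matrix: object
    genetic_map: object
    tags: list
    reduced_tags: list
    snps: list
    truth: object
    statistics: object
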