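"""End-to-end orchestration: filter -> QC -> consensus -> counts -> DA -> annotation.

Stages communicate through plain files (BED/TSV/JSON) and a manifest of
SHA-256 checksums; every stage is deterministic, so re-running an identical
configuration reproduces byte-identical outputs (the idempotence contract
asserted by the test suite). Stage-level logging records record counts in
and out of each filter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import annotation, consensus, counts, differential, organoid, qc
from .intervals import (
    DEFAULT_EXCLUDED_CHROMS,
    filter_chromosomes,
    read_bed,
    read_chrom_sizes,
    read_fasta,
    read_fragments,
    read_pwms,
    read_tss_table,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Stage parameters; defaults are the study's printed values."""

    data_dir: str = "."
    sample_sheet: str = "sample_sheet.tsv"
    chrom_sizes: str = "chrom.sizes"
    tss_table: str = "tss.tsv"
    genome_fasta: str = "genome.fa"
    pwm_library: str = "pwms.json"
    swelling_csv: str = "swelling.csv"
    boxes_csv: str = "boxes.csv"
    out_dir: str = "results"
    excluded_chroms: List[str] = field(default_factory=lambda: sorted(DEFAULT_EXCLUDED_CHROMS))
    min_support: int = 3
    frag_len: int = 64
    lfc_threshold: float = 1.0
    padj_threshold: float = 0.1
    proximal_up: int = 5000
    proximal_down: int = 1000
    distal_cap: int = 1_000_000
    motif_window: int = 200
    motif_mask: bool = True
    dispersion_method: str = "per-peak"
    strict_universal: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: Path, config: PipelineConfig, outputs: List[Path]) -> Path:
    cfg_text = json.dumps(dataclasses.asdict(config), sort_keys=True)
    manifest = {
        "tool": "airway-epi 0.1.0",
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


def read_sample_sheet(path, data_dir: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "donor_id", "peaks_bed", "fragments_bed"}
    missing = required - set(df.columns)
    if missing:
        raise PipelineError("sample_sheet", f"missing columns {sorted(missing)}")
    if df.empty:
        raise PipelineError("sample_sheet", "no samples listed")
    return df


def run_atac_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute the full ATAC arm; returns in-memory results and writes TSVs."""
    data_dir = Path(config.data_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: List[Path] = []

    sheet = read_sample_sheet(data_dir / config.sample_sheet, data_dir)
    sizes = read_chrom_sizes(data_dir / config.chrom_sizes)
    tss = read_tss_table(data_dir / config.tss_table)
    excluded = set(config.excluded_chroms)

    # --- load + chromosome filter
    rep_sets: List[consensus.ReplicatePeakSet] = []
    fragments: Dict[str, list] = {}
    group_samples: Dict[str, List[str]] = {}
    for row in sheet.itertuples():
        peaks = read_bed(data_dir / row.peaks_bed)
        kept = filter_chromosomes(peaks, excluded)
        logger.info("filter %s: peaks %d -> %d", row.sample_id, len(peaks), len(kept))
        rep_sets.append(
            consensus.ReplicatePeakSet(row.sample_id, row.group, row.donor_id, kept)
        )
        frs = read_fragments(data_dir / row.fragments_bed, row.sample_id)
        frs_kept = filter_chromosomes(frs, excluded)
        logger.info("filter %s: fragments %d -> %d", row.sample_id, len(frs), len(frs_kept))
        fragments[row.sample_id] = frs_kept
        group_samples.setdefault(row.group, []).append(row.sample_id)
    if len(group_samples) != 2:
        raise PipelineError("consensus", f"need 2 groups, got {sorted(group_samples)}")

    # --- QC: TSS enrichment per sample
    qc_rows = []
    for sample, frs in fragments.items():
        profile = qc.tss_profile(
            frs, tss, frag_len=config.frag_len, chrom_sizes=sizes, sample_id=sample
        )
        enr = qc.tss_enrichment(profile)
        qc_rows.append(
            {
                "sample_id": sample,
                "tss_signal": enr.tss_signal,
                "background_signal": enr.background_signal,
                "ratio": enr.ratio,
            }
        )
    qc_df = pd.DataFrame(qc_rows)
    qc_path = out_dir / "qc_tss_enrichment.tsv"
    qc_df.to_csv(qc_path, sep="\t", index=False, float_format="%.6g")
    outputs.append(qc_path)

    # --- consensus / reproducible / universal peaks
    merged = consensus.merge_intervals(rep_sets)
    groups = sorted(group_samples)
    for g in groups:
        consensus.reproducible_peaks(merged, g, group_samples, config.min_support)
    universe = consensus.analysis_peak_universe(merged, groups)
    universal = consensus.universal_peaks(
        merged, groups, strict_all_samples=config.strict_universal
    )
    logger.info(
        "consensus: %d merged, %d reproducible universe, %d universal",
        len(merged),
        len(universe),
        len(universal),
    )
    cons_path = out_dir / "consensus_peaks.tsv"
    with open(cons_path, "w") as fh:
        cols = ["peak_id", "chrom", "start", "end"]
        cols += [f"support_{g}" for g in groups]
        cols += [f"reproducible_{g}" for g in groups] + ["universal"]
        fh.write("\t".join(cols) + "\n")
        for p in merged:
            row = [p.peak_id, p.region.chrom, str(p.region.start), str(p.region.end)]
            row += [str(p.support_count(group_samples[g])) for g in groups]
            row += [str(int(p.group_reproducible[g])) for g in groups]
            row += [str(int(p.universal))]
            fh.write("\t".join(row) + "\n")
    outputs.append(cons_path)

    # --- counts + anchored normalization
    matrix = counts.count_fragments(universe, fragments)
    anchor = {p.peak_id for p in universal if p.peak_id in set(matrix.peak_ids)}
    if not anchor:
        raise PipelineError("normalize", "no universal peaks to anchor on")
    factors = counts.anchored_size_factors(matrix, anchor)
    normalized = counts.normalize(matrix, factors)

    counts_path = out_dir / "counts.tsv"
    pd.DataFrame(
        matrix.counts, index=matrix.peak_ids, columns=matrix.sample_ids
    ).to_csv(counts_path, sep="\t", index_label="peak_id")
    outputs.append(counts_path)
    sf_path = out_dir / "size_factors.tsv"
    with open(sf_path, "w") as fh:
        fh.write("sample_id\tsize_factor\n")
        for s in matrix.sample_ids:
            fh.write(f"{s}\t{factors.factors[s]:.8g}\n")
    outputs.append(sf_path)

    # --- differential accessibility
    design = dict(zip(sheet["sample_id"], sheet["group"]))
    disps = differential.estimate_dispersion(
        matrix, factors, design, method=config.dispersion_method
    )
    results = differential.wald_test(matrix, factors, disps, design)
    partition = differential.call_significant(
        results, config.lfc_threshold, config.padj_threshold
    )
    da_path = out_dir / "differential_accessibility.tsv"
    pd.DataFrame(
        [
            {
                "peak_id": r.peak_id,
                "baseMean": r.baseMean,
                "log2FC": r.log2FC,
                "se": r.se,
                "p": r.p,
                "padj": r.padj,
                "significant": int(r.significant),
                "direction": r.direction if r.significant else "",
            }
            for r in results
        ]
    ).to_csv(da_path, sep="\t", index=False, float_format="%.6g")
    outputs.append(da_path)

    # --- peak -> gene assignment
    domains = annotation.build_regulatory_domains(
        tss, sizes, config.proximal_up, config.proximal_down, config.distal_cap
    )
    assignment = annotation.assign_peaks_to_genes(universe, domains)
    assign_path = out_dir / "peak_gene_assignment.tsv"
    with open(assign_path, "w") as fh:
        fh.write("peak_id\tgene_ids\n")
        for pid in matrix.peak_ids:
            fh.write(f"{pid}\t{','.join(assignment.get(pid, []))}\n")
    outputs.append(assign_path)

    # --- motif enrichment on group-specific peaks
    genome = read_fasta(data_dir / config.genome_fasta)
    pwms = read_pwms(data_dir / config.pwm_library)
    sig_ids = {r.peak_id for r in results if r.significant}
    by_id = {p.peak_id: p for p in universe}
    motif_results = {}
    for g in groups:
        fg = [by_id[r.peak_id] for r in results if r.significant and r.direction == g]
        bg = [p for p in universe if p.peak_id not in sig_ids]
        if not fg:
            logger.info("motifs: no %s-specific peaks; skipping", g)
            continue
        motif_results[g] = annotation.motif_enrichment(
            fg, bg, genome, pwms, window=config.motif_window, mask=config.motif_mask
        )
    motif_path = out_dir / "motif_enrichment.tsv"
    with open(motif_path, "w") as fh:
        fh.write("group\tmotif_id\tfg_hits\tfg_total\tbg_hits\tbg_total\tp\tpadj\n")
        for g, res in motif_results.items():
            for r in sorted(res, key=lambda r: (r.padj, r.p, r.motif_id)):
                fh.write(
                    f"{g}\t{r.motif_id}\t{r.fg_hits}\t{r.fg_total}\t{r.bg_hits}"
                    f"\t{r.bg_total}\t{r.p:.6g}\t{r.padj:.6g}\n"
                )
    outputs.append(motif_path)

    write_manifest(out_dir, config, outputs)
    return {
        "qc": qc_df,
        "consensus": merged,
        "universe": universe,
        "universal": universal,
        "matrix": matrix,
        "factors": factors,
        "normalized": normalized,
        "results": results,
        "partition": partition,
        "assignment": assignment,
        "motifs": motif_results,
    }


def run_organoid_pipeline(config: PipelineConfig) -> Dict[str, pd.DataFrame]:
    """FIS curves/AUC and bounding-box morphometry from the input CSVs."""
    data_dir = Path(config.data_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: List[Path] = []

    series = organoid.read_swelling_csv(data_dir / config.swelling_csv)
    fis = organoid.fis_table(series)
    fis_path = out_dir / "fis_curves.tsv"
    fis.to_csv(fis_path, sep="\t", index=False, float_format="%.6g")
    outputs.append(fis_path)

    auc = (
        fis.groupby(["condition", "well_id"], sort=True)["auc"].first().reset_index()
    )
    auc_path = out_dir / "fis_auc.tsv"
    auc.to_csv(auc_path, sep="\t", index=False, float_format="%.6g")
    outputs.append(auc_path)

    boxes = organoid.read_boxes_csv(data_dir / config.boxes_csv)
    wells = organoid.well_area_table(boxes)
    wells_path = out_dir / "organoid_well_areas.tsv"
    wells.to_csv(wells_path, sep="\t", index=False, float_format="%.6g")
    outputs.append(wells_path)

    write_manifest(out_dir, config, outputs)
    return {"fis": fis, "auc": auc, "well_areas": wells}
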