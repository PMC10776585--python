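"""End-to-end orchestration: read → filter → ratio → calibrate → flag →
annotate → summarize, with a provenance-stamped output bundle.

Outputs written to the run directory:

* ``variants.tsv`` — per-variant results (identity, region, counts, ratio,
  log2 ratio, high-ratio flag, carrier profile) with a commented header
  block carrying the tool version and a config hash;
* ``threshold.json`` — the calibrated threshold and its provenance;
* ``summary_by_chrom.tsv`` — per-chromosome ratio summaries (n, mean, SD,
  min, max on both scales, one-decimal report rounding);
* ``findings.json`` / ``findings.txt`` — the five annotation tallies, when
  annotation tables are supplied;
* ``run_log.json`` — record counts at every stage;
* ``config.yaml`` — the resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import pandas as pd
import yaml

from . import __version__
from .annotation import join_annotations, read_annotation_table, summarize_findings
from .io import (
    TableReadResult,
    VariantRecord,
    filter_by_allele_count,
    read_count_table,
    read_vcf_counts,
)
from .ratio import RatioResult, RatioSummary, summarize_ratios
from .regions import GenomicRegionMap
from .threshold import ThresholdMethod, ThresholdResult, calibrate_threshold, score_and_flag

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "results_frame"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    input_path: str
    out_dir: str
    input_format: str = "table"  # "table" | "vcf"
    build: str = "grch38"
    par_file: Optional[str] = None
    min_ac: int = 5
    threshold_method: str = "par-max"
    threshold_quantile: Optional[float] = None
    threshold_value: Optional[float] = None
    annotations_path: Optional[str] = None
    regulome_path: Optional[str] = None
    include_autosomes: bool = False
    rarity_fraction: float = 1e-4

    def region_map(self) -> GenomicRegionMap:
        if self.par_file:
            return GenomicRegionMap.from_yaml(self.par_file)
        return GenomicRegionMap.from_build(self.build)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """In-memory view of a pipeline run plus the paths it wrote."""

    config: RunConfig
    records: List[VariantRecord]
    results: List[RatioResult]
    threshold: ThresholdResult
    variants_path: Path
    run_log: dict
    findings: Optional[dict] = None


def results_frame(records: List[VariantRecord], results: List[RatioResult]) -> pd.DataFrame:
    """Tabulate aligned records and ratio results."""
    rows = []
    for rec, res in zip(records, results):
        rows.append(
            {
                "variant_id": rec.variant_id,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "region": rec.region.value,
                "v_f": rec.counts.v_f,
                "a_f": rec.counts.a_f,
                "v_m": rec.counts.v_m,
                "a_m": rec.counts.a_m,
                "hom_f": rec.counts.hom_f,
                "hemi_m": rec.counts.hemi_m,
                "ratio": res.ratio,
                "log2_ratio": res.log2_ratio,
                "high_ratio": res.high_ratio,
                "carrier_profile": res.carrier_profile.value,
            }
        )
    return pd.DataFrame(rows)


def _write_tsv_with_header(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = (
        f"# fmratio {__version__}\n"
        f"# config_hash: {config.config_hash()}\n"
        f"# threshold_method: {config.threshold_method}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, na_rep="")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and write the output bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    region_map = config.region_map()
    run_log: dict = {"stages": {}, "config_hash": config.config_hash(), "version": __version__}

    # --- read ---------------------------------------------------------
    if config.input_format == "table":
        read_result: TableReadResult = read_count_table(config.input_path, region_map=region_map)
    elif config.input_format == "vcf":
        read_result = read_vcf_counts(config.input_path, region_map=region_map)
    else:
        raise ValueError(f"[read] unknown input format {config.input_format!r}")
    records = read_result.records
    run_log["stages"]["read"] = {
        "records": len(records),
        "rejected_rows": len(read_result.errors),
    }

    # --- allele-count filter ------------------------------------------
    filtered = filter_by_allele_count(records, min_ac=config.min_ac)
    run_log["stages"]["allele_count_filter"] = {
        "min_ac": config.min_ac,
        "kept": len(filtered),
        "dropped": len(records) - len(filtered),
    }
    if not filtered:
        logger.warning("no variants pass the allele-count filter; writing empty outputs")

    # --- calibrate ----------------------------------------------------
    if not filtered and config.threshold_value is None:
        # Nothing to calibrate on and nothing to flag: degenerate but valid.
        threshold = ThresholdResult(
            threshold=float("inf"), n_par=0, max_par_ratio=float("nan"),
            method=ThresholdMethod.FIXED,
        )
    else:
        try:
            threshold = calibrate_threshold(
                filtered,
                method=ThresholdMethod(config.threshold_method),
                quantile=config.threshold_quantile,
                fixed_value=config.threshold_value,
            )
        except ValueError as exc:
            raise ValueError(f"[calibrate] {exc}") from exc
    run_log["stages"]["calibrate"] = threshold.to_dict()

    # --- score and flag -----------------------------------------------
    results = score_and_flag(
        filtered,
        threshold.threshold,
        include_autosomes=config.include_autosomes,
        rarity_fraction=config.rarity_fraction,
    )
    n_flagged = sum(r.high_ratio for r in results)
    run_log["stages"]["flag"] = {"threshold": threshold.threshold, "flagged": n_flagged}

    df = results_frame(filtered, results)
    variants_path = out_dir / "variants.tsv"
    _write_tsv_with_header(df, variants_path, config)

    # --- per-chromosome summaries -------------------------------------
    summary_rows = []
    if len(df):
        for chrom, group in df.groupby("chrom", sort=True):
            row = summarize_ratios(group["ratio"]).to_report_row()
            row = {"chrom": chrom, **row}
            summary_rows.append(row)
    summary_columns = ["chrom", *RatioSummary.REPORT_COLUMNS]
    summary_df = pd.DataFrame(summary_rows, columns=summary_columns)
    _write_tsv_with_header(summary_df, out_dir / "summary_by_chrom.tsv", config)
    run_log["stages"]["summaries"] = {"chromosomes": len(summary_rows)}

    with open(out_dir / "threshold.json", "w") as fh:
        json.dump(threshold.to_dict(), fh, indent=2)

    # --- annotation findings ------------------------------------------
    findings = None
    if config.annotations_path:
        annotations = read_annotation_table(
            config.annotations_path, regulome_path=config.regulome_path
        )
        # The annotation tables describe the flagged candidate set; the five
        # tallies are therefore computed over the whole table, while the join
        # reports this run's coverage of it.
        summary = summarize_findings(annotations)
        findings = summary.to_dict()
        flagged_results = [r for r in results if r.high_ratio]
        findings["n_flagged"] = len(flagged_results)
        if flagged_results:
            joined = join_annotations(flagged_results, annotations)
            _write_tsv_with_header(joined, out_dir / "flagged_annotated.tsv", config)
            findings["n_flagged_unannotated"] = int((~joined["annotated"]).sum())
        else:
            logger.warning("no flagged variants to annotate")
        (out_dir / "findings.txt").write_text(summary.to_text() + "\n")
        with open(out_dir / "findings.json", "w") as fh:
            json.dump(findings, fh, indent=2)
        run_log["stages"]["annotate"] = {
            "annotations": len(annotations),
            "flagged": len(flagged_results),
        }

    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    return PipelineResult(
        config=config,
        records=filtered,
        results=results,
        threshold=threshold,
        variants_path=variants_path,
        run_log=run_log,
        findings=findings,
    )
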