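"""YAML-driven orchestration of the per-sample analysis sequence.

A single configuration file names the annotation, the samples and the
parameters; ``run_pipeline`` then executes, per sample and in order:
optional 5'-mismatch trimming -> optional exact UMI deduplication ->
alignment filtering -> ribogrid build + H5 -> summaries (length
distribution, frame proportions, metagene, codon densities, gene counts,
TPM, optional codon-feature correlation) -> plots -> HTML report.

Alignment itself is external: samples are supplied as transcriptome BAMs
(or produced by a user-configured aligner command); this package never
bundles an aligner.  A failed sample is recorded in the run manifest and
does not abort the others.  With a fixed seed and no timestamp configured,
re-running an identical config reproduces byte-identical H5 and TSV
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shlex
import subprocess
import traceback
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from . import __version__
from .annotation import load_annotation, validate_annotation, write_validation_report
from .asite import EUKARYOTE_PRESET, AsiteOffsetTable, load_offsets
from .grid import build_ribogrid, write_length_counts_tsv, write_ribogrid_h5
from .postprocess import filter_alignments, trim_bam
from .preprocess import dedup_exact, demultiplex, load_barcode_sheet, read_fastq
from .summaries import (
    SENSE_CODONS,
    codon_densities_for_sample,
    codon_feature_correlation,
    frame_proportions_per_gene,
    gene_counts_and_tpm,
    length_distribution,
    metagene_profile,
)
from .viz import (
    plot_codon_feature,
    plot_frame_proportions,
    plot_length_distribution,
    plot_metagene,
    plot_ribogrid_heatmap,
    render_html_report,
)

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(errors))


class RunConfig(BaseModel):
    """Validated run configuration (unknown keys are rejected by name)."""

    model_config = ConfigDict(extra="forbid")

    fasta: Path
    gff3: Path
    samples: dict[str, Path]
    output_dir: Path = Path("ribogridkit_out")

    offsets: Optional[Path] = None
    asite_anchor: str = "five_prime"
    barcode_sheet: Optional[Path] = None
    trna_table: Optional[Path] = None
    aligner_command: Optional[str] = None

    demultiplex: bool = False
    trim_5p: bool = False
    dedup: bool = False

    min_length: int = 10
    max_length: int = 50
    max_trim: int = 2
    max_mismatches: int = 1
    min_reads: int = 64
    metagene_window: int = 25
    umi5_length: int = 0
    umi3_length: int = 0
    seed: int = 0
    timestamp: Optional[str] = None

    @field_validator("asite_anchor")
    @classmethod
    def _anchor_ok(cls, v: str) -> str:
        if v not in ("five_prime", "three_prime"):
            raise ValueError("asite_anchor must be five_prime or three_prime")
        return v

    def semantic_errors(self, check_paths: bool = True) -> list[str]:
        errors = []
        if self.min_length > self.max_length:
            errors.append(
                f"min_length ({self.min_length}) > max_length "
                f"({self.max_length})"
            )
        for name, bound in [
            ("max_trim", self.max_trim), ("max_mismatches", self.max_mismatches),
            ("min_reads", self.min_reads), ("umi5_length", self.umi5_length),
            ("umi3_length", self.umi3_length),
        ]:
            if bound < 0:
                errors.append(f"{name} must be >= 0, got {bound}")
        if self.metagene_window < 1:
            errors.append("metagene_window must be >= 1")
        if not self.samples:
            errors.append("no samples configured")
        if check_paths:
            for label, p in [
                ("fasta", self.fasta), ("gff3", self.gff3),
                ("offsets", self.offsets), ("barcode_sheet", self.barcode_sheet),
                ("trna_table", self.trna_table),
            ]:
                if p is not None and not Path(p).exists():
                    errors.append(f"{label} file not found: {p}")
            for name, p in self.samples.items():
                if not Path(p).exists():
                    errors.append(f"sample {name!r}: input not found: {p}")
        return errors


def validate_config(path: str | Path) -> tuple[RunConfig | None, list[str]]:
    """Parse and validate a YAML config, returning the full error list."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        return None, [f"cannot read config: {exc}"]
    try:
        config = RunConfig(**raw)
    except ValidationError as exc:
        return None, [
            f"{'.'.join(str(x) for x in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
    errors = config.semantic_errors()
    return (config if not errors else None), errors


def load_config(path: str | Path) -> RunConfig:
    config, errors = validate_config(path)
    if errors:
        raise ConfigError(errors)
    assert config is not None
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_trna_table(path: Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if "codon" not in cols or len(cols) < 2:
        raise ConfigError([f"tRNA table {path} needs columns: codon, value"])
    value_col = [c for c in cols if c != "codon"][0]
    table = dict(zip(df["codon"].str.upper(), df[value_col].astype(float)))
    missing = [c for c in SENSE_CODONS if c not in table]
    if missing:
        raise ConfigError(
            [f"tRNA table missing {len(missing)} sense codons ({missing[:5]})"]
        )
    return table


def _align_sample(config: RunConfig, name: str, fastq: Path, outdir: Path) -> Path:
    """Run the user-configured external aligner command (FASTQ -> BAM)."""
    if config.aligner_command is None:
        raise ConfigError(
            [f"sample {name!r} is FASTQ but no aligner_command is configured"]
        )
    bam = outdir / f"{name}.aligned.bam"
    cmd = [
        arg.format(fastq=str(fastq), bam=str(bam), fasta=str(config.fasta))
        for arg in shlex.split(config.aligner_command)
    ]
    subprocess.run(cmd, check=True)
    return bam


def process_sample(
    config: RunConfig,
    name: str,
    bam_path: Path,
    annotation,
    offsets: AsiteOffsetTable,
    trna: dict[str, float] | None,
    outdir: Path,
) -> dict:
    """Run the full post-alignment analysis for one sample."""
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    current = Path(bam_path)

    if config.trim_5p:
        trimmed = outdir / f"{name}.trimmed.bam"
        discarded = outdir / f"{name}.trim_discarded.bam"
        summary = trim_bam(current, trimmed, discarded, config.max_trim)
        summary.to_frame().to_csv(
            outdir / f"{name}.trim_summary.tsv", sep="\t", index=False
        )
        outputs["trimmed_bam"] = str(trimmed)
        outputs["trim_summary"] = str(outdir / f"{name}.trim_summary.tsv")
        current = trimmed

    if config.dedup:
        deduped = outdir / f"{name}.dedup.bam"
        kept, removed = dedup_exact(current, deduped)
        (outdir / f"{name}.dedup_stats.tsv").write_text(
            f"kept\tremoved\n{kept}\t{removed}\n"
        )
        outputs["dedup_bam"] = str(deduped)
        current = deduped

    footprints, report = filter_alignments(
        current, annotation, config.min_length, config.max_length
    )
    report.to_frame().to_csv(
        outdir / f"{name}.filter_report.tsv", sep="\t", index=False
    )
    outputs["filter_report"] = str(outdir / f"{name}.filter_report.tsv")

    grids = build_ribogrid(
        footprints, annotation, config.min_length, config.max_length
    )
    h5_path = outdir / f"{name}.h5"
    write_ribogrid_h5(
        grids, annotation, h5_path, sample_name=name,
        source_bam=Path(bam_path).name, timestamp=config.timestamp,
    )
    outputs["ribogrid_h5"] = str(h5_path)
    write_length_counts_tsv(grids, outdir / f"{name}.length_counts.tsv")
    outputs["length_counts"] = str(outdir / f"{name}.length_counts.tsv")

    frame_table = frame_proportions_per_gene(
        grids, annotation, offsets, config.min_reads
    )
    frame_table.to_csv(
        outdir / f"{name}.frame_proportions.tsv", sep="\t", index=False
    )
    outputs["frame_proportions"] = str(outdir / f"{name}.frame_proportions.tsv")

    profile = metagene_profile(
        grids, annotation, "start_codon", config.metagene_window
    )
    profile.to_frame().to_csv(
        outdir / f"{name}.metagene.tsv", sep="\t", index=False
    )
    outputs["metagene"] = str(outdir / f"{name}.metagene.tsv")

    densities, _exclusions = codon_densities_for_sample(
        grids, annotation, offsets
    )
    quant = gene_counts_and_tpm(densities, annotation)
    quant.to_csv(outdir / f"{name}.gene_quant.tsv", sep="\t", index=False)
    outputs["gene_quant"] = str(outdir / f"{name}.gene_quant.tsv")

    corr_table = None
    if trna is not None:
        corr = codon_feature_correlation(
            densities, annotation, trna,
            min_reads=config.min_reads, seed=config.seed,
        )
        corr_table = corr.table
        corr.table.to_csv(
            outdir / f"{name}.codon_feature.tsv", sep="\t", index=False
        )
        (outdir / f"{name}.codon_feature_stats.tsv").write_text(
            f"rho\tp_value\tn_genes\n{corr.rho}\t{corr.p_value}\t{corr.n_genes}\n"
        )
        outputs["codon_feature"] = str(outdir / f"{name}.codon_feature.tsv")

    # plots + report
    dist = length_distribution(grids)
    plots: dict[str, Path] = {}
    plots["length_distribution"] = plot_length_distribution(
        dist, outdir / f"{name}.length_distribution.png"
    )
    plots["frame_proportions"] = plot_frame_proportions(
        frame_table, outdir / f"{name}.frame_proportions.png"
    )
    plots["metagene"] = plot_metagene(profile, outdir / f"{name}.metagene.png")
    busiest = max(grids, key=lambda t: grids[t].total)
    if grids[busiest].total > 0:
        plots["ribogrid_heatmap"] = plot_ribogrid_heatmap(
            grids[busiest], annotation, outdir / f"{name}.ribogrid.png"
        )
    if corr_table is not None:
        plots["codon_feature"] = plot_codon_feature(
            corr_table, outdir / f"{name}.codon_feature.png"
        )
    report_path = render_html_report(
        name,
        plots,
        tables={"Gene quantification (head)": quant},
        out_html=outdir / f"{name}.html",
        timestamp=config.timestamp,
        metadata={
            "tool_version": __version__,
            "input_bam": Path(bam_path).name,
            "accepted_footprints": report.n_accepted,
        },
    )
    outputs["html_report"] = str(report_path)
    return outputs


def run_pipeline(config: RunConfig) -> dict:
    """Execute every enabled stage for every sample; write a run manifest.

    Returns the manifest dict; per-sample failures are recorded under
    ``samples.<name>.status`` without aborting other samples.
    """
    errors = config.semantic_errors()
    if errors:
        raise ConfigError(errors)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    annotation = load_annotation(config.fasta, config.gff3)
    write_validation_report(
        validate_annotation(annotation), outdir / "annotation_report.tsv"
    )
    offsets = (
        load_offsets(config.offsets, config.asite_anchor)
        if config.offsets is not None
        else EUKARYOTE_PRESET
    )
    trna = _load_trna_table(config.trna_table) if config.trna_table else None

    manifest: dict = {
        "tool_version": __version__,
        "parameters": json.loads(config.model_dump_json()),
        "inputs": {
            "fasta": {"path": str(config.fasta), "sha256": _sha256(config.fasta)},
            "gff3": {"path": str(config.gff3), "sha256": _sha256(config.gff3)},
        },
        "samples": {},
    }
    if config.timestamp is not None:
        manifest["timestamp"] = config.timestamp

    for name, input_path in config.samples.items():
        sample_dir = outdir / name
        entry: dict = {
            "input": {"path": str(input_path), "sha256": _sha256(Path(input_path))}
        }
        try:
            input_path = Path(input_path)
            if input_path.suffix in (".fastq", ".fq", ".gz"):
                if config.demultiplex:
                    if config.barcode_sheet is None:
                        raise ConfigError(
                            ["demultiplex enabled but no barcode_sheet given"]
                        )
                    sheet = load_barcode_sheet(
                        config.barcode_sheet, config.max_mismatches
                    )
                    counts = demultiplex(
                        read_fastq(input_path), sheet, sample_dir / "demux"
                    )
                    entry["demultiplex_counts"] = dict(counts)
                bam = _align_sample(config, name, input_path, sample_dir)
            else:
                bam = input_path
            entry["outputs"] = process_sample(
                config, name, bam, annotation, offsets, trna, sample_dir
            )
            entry["status"] = "ok"
        except Exception as exc:  # per-sample isolation is the contract
            log.error("sample %s failed: %s", name, exc)
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            entry["traceback"] = traceback.format_exc(limit=5)
        manifest["samples"][name] = entry

    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
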