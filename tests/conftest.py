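"""Shared fixtures: tiny hand-built annotations and seeded simulations."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from ribogridkit.annotation import AnnotationSet, TranscriptAnnotation, load_annotation
from ribogridkit.simulate import (
    SimulationSpec,
    simulate_footprints,
    simulate_transcriptome,
)


def write_fasta(path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def write_gff3(path, rows: list[tuple]) -> None:
    """rows: (seqid, feature, start_1based, end_1based[, strand])."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, row in enumerate(rows):
            seqid, feature, start, end = row[:4]
            strand = row[4] if len(row) > 4 else "+"
            fh.write(
                f"{seqid}\ttest\t{feature}\t{start}\t{end}\t.\t{strand}\t0"
                f"\tID={feature}:{seqid}:{i}\n"
            )


def make_sequence(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture
def t1_annotation() -> AnnotationSet:
    """One 60 nt transcript with a 30 nt CDS at [15, 45)."""
    seq = make_sequence(15) + "ATG" + make_sequence(24, seed=1) + "TAA" + make_sequence(15, seed=2)
    ann = AnnotationSet()
    ann.add(TranscriptAnnotation("T1", seq, 15, 45))
    return ann


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory) -> tuple:
    """A small clean library: 20 genes, 5,000 molecules, no artefacts."""
    outdir = tmp_path_factory.mktemp("sim_small")
    spec = SimulationSpec(n_transcripts=20, depth=5000, seed=11)
    annotation = simulate_transcriptome(
        spec, outdir / "t.fasta", outdir / "t.gff3"
    )
    result = simulate_footprints(spec, annotation, outdir)
    return spec, annotation, result, outdir


@pytest.fixture(scope="session")
def sim_messy(tmp_path_factory) -> tuple:
    """A library with every artefact on: 5' additions, PCR duplicates, UMIs."""
    outdir = tmp_path_factory.mktemp("sim_messy")
    spec = SimulationSpec(
        n_transcripts=15,
        depth=3000,
        seed=7,
        p_5p_addition=0.3,
        pcr_duplication=1.6,
        umi_length=8,
    )
    annotation = simulate_transcriptome(
        spec, outdir / "t.fasta", outdir / "t.gff3"
    )
    result = simulate_footprints(spec, annotation, outdir)
    return spec, annotation, result, outdir


def make_bam_record(
    header: pysam.AlignmentHeader,
    name: str,
    ref_id: int,
    pos: int,
    seq: str,
    md: str | None = None,
    nm: int | None = None,
    flag: int = 0,
) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.query_sequence = seq
    rec.flag = flag
    rec.reference_id = ref_id
    rec.reference_start = pos
    rec.mapping_quality = 255
    if not rec.is_unmapped:
        rec.cigartuples = [(0, len(seq))]
    rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    if md is not None:
        rec.set_tag("MD", md)
    if nm is not None:
        rec.set_tag("NM", nm)
    return rec


def bam_header(annotation: AnnotationSet) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [
                {"SN": t.transcript_id, "LN": t.length} for t in annotation
            ],
        }
    )
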