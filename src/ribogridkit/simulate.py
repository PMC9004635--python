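"""Synthetic transcriptomes and footprint libraries with known ground truth.

The generator emulates a padded-ORFeome Ribo-seq experiment: transcripts are
built as pad + ATG + random sense codons + stop + pad, and footprints are
drawn molecule by molecule with planted gene abundances, per-codon dwell
times, read-length distribution, reading-frame weights and A-site
displacements.  Optional library artefacts — non-templated 5' additions,
PCR duplication with UMIs, sample barcodes with sequencing errors — are
applied on top, and every draw is recorded in a manifest, so each pipeline
stage has an exact (counts) or statistical (proportions) oracle.

The BAM is written directly as if perfectly aligned (positions are ground
truth; CIGAR/MD/NM are internally consistent), so no aligner is involved.
All randomness flows from one seed through named child streams: the
molecule draw is independent of the artefact draws, which makes e.g. a
p_5p_addition > 0 sample and its p = 0 control share identical molecules —
a paired design for measuring the effect of 5' trimming.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
import yaml

from .annotation import AnnotationSet, TranscriptAnnotation, write_annotation
from .asite import AsiteOffsetTable, EUKARYOTE_PRESET
from .postprocess import encode_md
from .summaries import SENSE_CODONS

_NT = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")

# Child-stream tags: one independent generator per source of randomness.
_STREAM_TRANSCRIPTOME = 101
_STREAM_MOLECULES = 202
_STREAM_ADDITIONS = 303
_STREAM_PCR_UMI = 404
_STREAM_BARCODES = 505


class SimulationError(ValueError):
    pass


def _default_length_weights() -> dict[int, float]:
    return {26: 0.05, 27: 0.10, 28: 0.40, 29: 0.20, 30: 0.15, 31: 0.05, 32: 0.05}


@dataclasses.dataclass
class SimulationSpec:
    """All knobs of one simulated experiment (ground truth by construction)."""

    n_transcripts: int = 100
    cds_codon_range: tuple[int, int] = (100, 300)
    pad_length: int = 50
    length_weights: dict[int, float] = dataclasses.field(
        default_factory=_default_length_weights
    )
    frame_weights: tuple[float, float, float] = (0.85, 0.10, 0.05)
    offsets: AsiteOffsetTable = dataclasses.field(
        default_factory=lambda: EUKARYOTE_PRESET
    )
    per_codon_dwell: dict[str, float] | None = None
    depth: int = 20_000
    p_5p_addition: float = 0.0
    pcr_duplication: float = 1.0
    umi_length: int = 0
    barcodes: dict[str, str] | None = None
    barcode_mutation_weights: tuple[float, float, float] = (1.0, 0.0, 0.0)
    abundance_sigma: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.length_weights.values()) - 1.0) > 1e-9:
            raise SimulationError("length_weights must sum to 1")
        if abs(sum(self.frame_weights) - 1.0) > 1e-9:
            raise SimulationError("frame_weights must sum to 1")
        if not 0.0 <= self.p_5p_addition <= 1.0:
            raise SimulationError("p_5p_addition must be a probability")
        if self.pcr_duplication < 1.0:
            raise SimulationError("pcr_duplication is a mean >= 1")
        if self.per_codon_dwell is not None:
            if any(v <= 0 for v in self.per_codon_dwell.values()):
                raise SimulationError("per-codon dwell rates must be > 0")
        for length in self.length_weights:
            if length not in self.offsets.offsets:
                raise SimulationError(
                    f"read length {length} has weight but no planted offset"
                )
        # The pads must absorb the largest 5'/3' overhang any footprint can
        # have, otherwise a planted (offset, length) walks off the transcript.
        need5 = need3 = 0
        for length, w in self.length_weights.items():
            d = self.offsets.offsets[length]
            if self.offsets.anchor == "five_prime":
                up, down = d, length - 1 - d
            else:
                up, down = length - 1 - d, d
            need5, need3 = max(need5, up), max(need3, down)
        slack = 2 if self.p_5p_addition > 0 else 0
        if self.pad_length < max(need5 + slack, need3):
            raise SimulationError(
                f"pad_length {self.pad_length} too short for planted offsets "
                f"(need >= {max(need5 + slack, need3)})"
            )

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["offsets"] = {
            "anchor": self.offsets.anchor, "offsets": self.offsets.offsets
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "offsets" in d:
            d["offsets"] = AsiteOffsetTable(
                d["offsets"]["anchor"],
                {int(k): int(v) for k, v in d["offsets"]["offsets"].items()},
            )
        for key in ("cds_codon_range", "frame_weights", "barcode_mutation_weights"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "length_weights" in d:
            d["length_weights"] = {
                int(k): float(v) for k, v in d["length_weights"].items()
            }
        return cls(**d)


def simulate_transcriptome(
    spec: SimulationSpec,
    fasta_path: str | Path | None = None,
    gff3_path: str | Path | None = None,
) -> AnnotationSet:
    """Generate a padded-ORFeome transcriptome (deterministic under seed).

    Each transcript is pad + ATG + (cds_codons - 2) random sense codons +
    stop + pad; the GFF3 CDS covers start through stop inclusive.
    """
    rng = np.random.default_rng([spec.seed, _STREAM_TRANSCRIPTOME])
    lo, hi = spec.cds_codon_range
    if lo < 3 or hi < lo:
        raise SimulationError("cds_codon_range must satisfy 3 <= lo <= hi")
    annotation = AnnotationSet()
    width = max(4, len(str(spec.n_transcripts)))
    for i in range(spec.n_transcripts):
        n_codons = int(rng.integers(lo, hi + 1))
        pad5 = "".join(_NT[rng.integers(0, 4, size=spec.pad_length)])
        pad3 = "".join(_NT[rng.integers(0, 4, size=spec.pad_length)])
        interior = "".join(
            SENSE_CODONS[j] for j in rng.integers(0, len(SENSE_CODONS),
                                                  size=n_codons - 2)
        )
        stop = _STOPS[int(rng.integers(0, 3))]
        seq = pad5 + "ATG" + interior + stop + pad3
        cds_start = spec.pad_length
        cds_end = cds_start + 3 * n_codons
        annotation.add(
            TranscriptAnnotation(f"T{i + 1:0{width}d}", seq, cds_start, cds_end)
        )
    if fasta_path is not None and gff3_path is not None:
        write_annotation(annotation, fasta_path, gff3_path)
    return annotation


@dataclasses.dataclass
class SimulationResult:
    """Everything one simulated sample produced, plus the ground truth."""

    spec: SimulationSpec
    annotation: AnnotationSet
    manifest: pd.DataFrame
    bam_path: Path
    fastq_path: Path | None = None
    abundances: pd.Series | None = None

    def expected_grid_tally(
        self, min_length: int, max_length: int, trimmed: bool = True
    ) -> dict[str, np.ndarray]:
        """Per-transcript (length x position) tallies implied by the manifest.

        ``trimmed=True`` uses the templated fragment coordinates (what the
        pipeline recovers after 5' mismatch trimming); ``False`` uses the
        as-aligned coordinates including non-templated additions.
        """
        pos_col = "pos5" if trimmed else "aln_pos5"
        len_col = "length" if trimmed else "aln_length"
        tallies = {
            t.transcript_id: np.zeros(
                (max_length - min_length + 1, t.length), dtype=np.int64
            )
            for t in self.annotation
        }
        for row in self.manifest.itertuples(index=False):
            length = getattr(row, len_col)
            if not min_length <= length <= max_length:
                continue
            tallies[row.transcript][length - min_length, getattr(row, pos_col)] += 1
        return tallies

    def expected_gene_counts(self, unique_molecules: bool = False) -> pd.Series:
        """Reads (or distinct molecules) per transcript, in annotation order."""
        df = self.manifest
        if unique_molecules:
            df = df.drop_duplicates(subset=["transcript", "molecule"])
        counts = df.groupby("transcript").size()
        return counts.reindex(self.annotation.ids(), fill_value=0)


def _mutate_barcode(
    barcode: str, n_mut: int, rng: np.random.Generator
) -> str:
    if n_mut == 0:
        return barcode
    positions = rng.choice(len(barcode), size=n_mut, replace=False)
    bc = list(barcode)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != bc[p]]
        bc[p] = alternatives[int(rng.integers(0, 3))]
    return "".join(bc)


def simulate_footprints(
    spec: SimulationSpec,
    annotation: AnnotationSet,
    outdir: str | Path,
    sample_name: str = "sim",
    write_fastq: bool | None = None,
) -> SimulationResult:
    """Draw a footprint library and write BAM (+ optional FASTQ) + manifest.

    Molecule model: gene ~ planted lognormal abundances; A-site codon within
    the gene ~ per-codon dwell of the codon identity (uniform when no dwell
    is planted; the stop codon is never an A-site); frame offset ~
    frame_weights; read length ~ length_weights; the 5' position follows by
    inverting the planted displacement.  Artefacts (5' additions, PCR
    copies, UMIs, barcodes) are layered per molecule/read afterwards from
    independent random streams.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_mol = np.random.default_rng([spec.seed, _STREAM_MOLECULES])
    rng_add = np.random.default_rng([spec.seed, _STREAM_ADDITIONS])
    rng_pcr = np.random.default_rng([spec.seed, _STREAM_PCR_UMI])
    rng_bc = np.random.default_rng([spec.seed, _STREAM_BARCODES])

    transcripts = list(annotation)
    n_tx = len(transcripts)
    abund = rng_mol.lognormal(0.0, spec.abundance_sigma, size=n_tx)
    abund /= abund.sum()

    # Per-gene codon-sampling distributions over sense codons (stop excluded).
    dwell = spec.per_codon_dwell
    codon_probs: list[np.ndarray] = []
    for t in transcripts:
        n_sense = t.n_codons - 1
        if dwell is None:
            codon_probs.append(np.full(n_sense, 1.0 / n_sense))
        else:
            w = np.array(
                [dwell.get(t.codon(c), 1.0) for c in range(n_sense)], float
            )
            codon_probs.append(w / w.sum())

    lengths_arr = np.array(sorted(spec.length_weights))
    length_p = np.array([spec.length_weights[l] for l in lengths_arr])

    # --- molecules -------------------------------------------------------
    gene_idx = rng_mol.choice(n_tx, size=spec.depth, p=abund)
    frames = rng_mol.choice(3, size=spec.depth, p=np.array(spec.frame_weights))
    lengths = lengths_arr[rng_mol.choice(len(lengths_arr), size=spec.depth,
                                         p=length_p)]
    codons = np.empty(spec.depth, dtype=np.int64)
    for g in range(n_tx):
        sel = np.nonzero(gene_idx == g)[0]
        if sel.size:
            codons[sel] = rng_mol.choice(
                len(codon_probs[g]), size=sel.size, p=codon_probs[g]
            )

    # --- artefact draws (independent streams) ----------------------------
    has_addition = rng_add.random(spec.depth) < spec.p_5p_addition
    n_added = np.where(has_addition, rng_add.integers(1, 3, size=spec.depth), 0)
    # base choices for up to 2 additions, resolved against the reference below
    add_choice = rng_add.integers(0, 3, size=(spec.depth, 2))

    if spec.pcr_duplication > 1.0:
        copies = 1 + rng_pcr.poisson(spec.pcr_duplication - 1.0, size=spec.depth)
    else:
        copies = np.ones(spec.depth, dtype=np.int64)
    umis = None
    if spec.umi_length > 0:
        umis = [
            "".join(_NT[rng_pcr.integers(0, 4, size=spec.umi_length)])
            for _ in range(spec.depth)
        ]

    sample_names = list(spec.barcodes) if spec.barcodes else [sample_name]
    mol_sample = (
        rng_bc.integers(0, len(sample_names), size=spec.depth)
        if spec.barcodes
        else np.zeros(spec.depth, dtype=np.int64)
    )
    bc_weights = np.array(spec.barcode_mutation_weights)
    bc_weights = bc_weights / bc_weights.sum()

    # --- realize reads ---------------------------------------------------
    rows: list[dict] = []
    bam_records: list[tuple[int, int, dict]] = []
    fastq_lines: list[str] = []
    if write_fastq is None:
        write_fastq = bool(spec.barcodes) or spec.umi_length > 0
    read_index = 0
    tx_index = {t.transcript_id: i for i, t in enumerate(transcripts)}
    for m in range(spec.depth):
        t = transcripts[gene_idx[m]]
        c, f, length = int(codons[m]), int(frames[m]), int(lengths[m])
        a = t.cds_start + 3 * c + f
        d = spec.offsets.offsets[length]
        if spec.offsets.anchor == "five_prime":
            pos5 = a - d
        else:
            pos5 = a + d - length + 1
        if pos5 < 0 or pos5 + length > t.length:
            raise SimulationError(
                f"planted offset incompatible with read length {length} "
                f"on {t.transcript_id}"
            )
        j = int(n_added[m])
        if pos5 - j < 0:
            j = 0
        added = ""
        if j:
            # each added base mismatches the reference base it aligns over
            bases = []
            for off in range(j):  # read offsets 0..j-1 -> ref pos5-j..pos5-1
                ref_base = t.sequence[pos5 - j + off]
                alternatives = [b for b in "ACGT" if b != ref_base]
                bases.append(alternatives[int(add_choice[m, off])])
            added = "".join(bases)
        fragment = t.sequence[pos5 : pos5 + length]
        read_seq = added + fragment
        aln_pos5 = pos5 - j
        aln_length = length + j
        md_entries: list[str | None] = [
            t.sequence[aln_pos5 + off] for off in range(j)
        ] + [None] * length
        md = encode_md(md_entries)
        umi = umis[m] if umis is not None else ""
        sname = sample_names[int(mol_sample[m])]
        barcode_true = spec.barcodes[sname] if spec.barcodes else ""
        first_read_of_molecule = read_index
        for copy in range(int(copies[m])):
            qname = f"r{read_index:08d}"
            if umi:
                qname = f"{qname}_{umi}"
            n_mut = int(rng_bc.choice(3, p=bc_weights)) if spec.barcodes else 0
            barcode_obs = (
                _mutate_barcode(barcode_true, n_mut, rng_bc)
                if spec.barcodes
                else ""
            )
            if write_fastq:
                fq_seq = barcode_obs + umi + read_seq
                fastq_lines.append(
                    f"@r{read_index:08d}\n{fq_seq}\n+\n{'I' * len(fq_seq)}\n"
                )
            bam_records.append(
                (
                    tx_index[t.transcript_id],
                    aln_pos5,
                    {
                        "qname": qname,
                        "seq": read_seq,
                        "md": md,
                        "nm": j,
                        "length": aln_length,
                    },
                )
            )
            rows.append(
                {
                    "read_id": qname,
                    "sample": sname,
                    "barcode": barcode_obs,
                    "barcode_mismatches": n_mut,
                    "transcript": t.transcript_id,
                    "molecule": m,
                    "is_duplicate": copy > 0,
                    "duplicate_of": (
                        f"r{first_read_of_molecule:08d}" if copy > 0 else ""
                    ),
                    "a_codon": c,
                    "a_pos": a,
                    "frame": f,
                    "length": length,
                    "pos5": pos5,
                    "n_added_5p": j,
                    "aln_pos5": aln_pos5,
                    "aln_length": aln_length,
                    "umi": umi,
                }
            )
            read_index += 1

    manifest = pd.DataFrame(
        rows,
        columns=[
            "read_id", "sample", "barcode", "barcode_mismatches",
            "transcript", "molecule", "is_duplicate", "duplicate_of",
            "a_codon", "a_pos", "frame", "length", "pos5", "n_added_5p",
            "aln_pos5", "aln_length", "umi",
        ],
    )

    # --- write outputs ---------------------------------------------------
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": t.transcript_id, "LN": t.length} for t in transcripts
            ],
            "PG": [{"ID": "ribogridkit-simulate", "PN": "ribogridkit"}],
            "CO": [f"simulation seed={spec.seed}"],
        }
    )
    bam_path = outdir / f"{sample_name}.bam"
    bam_records.sort(key=lambda rec: (rec[0], rec[1], rec[2]["qname"]))
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for ref_id, pos, fields in bam_records:
            rec = pysam.AlignedSegment(header)
            rec.query_name = fields["qname"]
            rec.query_sequence = fields["seq"]
            rec.query_qualities = pysam.qualitystring_to_array(
                "I" * len(fields["seq"])
            )
            rec.flag = 0
            rec.reference_id = ref_id
            rec.reference_start = pos
            rec.mapping_quality = 255
            rec.cigartuples = [(0, fields["length"])]
            rec.set_tag("MD", fields["md"])
            rec.set_tag("NM", fields["nm"])
            bam.write(rec)

    fastq_path = None
    if write_fastq:
        fastq_path = outdir / f"{sample_name}.fastq"
        fastq_path.write_text("".join(fastq_lines))

    manifest.to_csv(outdir / f"{sample_name}.manifest.tsv", sep="\t", index=False)
    return SimulationResult(
        spec=spec,
        annotation=annotation,
        manifest=manifest,
        bam_path=bam_path,
        fastq_path=fastq_path,
        abundances=pd.Series(abund, index=[t.transcript_id for t in transcripts]),
    )


def planted_dwell_from_feature(
    feature: Mapping[str, float]
) -> dict[str, float]:
    """Dwell rates inversely proportional to a per-codon feature.

    Models fast decoding of codons with abundant tRNAs: dwell = 1/feature,
    so recovered codon densities should rank-anticorrelate with the feature.
    """
    return {c: 1.0 / float(v) for c, v in feature.items() if float(v) > 0}
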