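"""Transcript-centric annotation: FASTA + GFF3 -> validated transcript models.

The inputs are a transcriptome FASTA (spliced transcripts with UTRs, or a
"padded ORFeome" built as ORFs with fixed-width flanks) and a GFF3 file that
places one open reading frame on each transcript.  Because the sequences are
transcripts, not chromosomes, every feature lies on the plus strand and there
is no exon/intron arithmetic.

All internal coordinates are 0-based half-open.  The 1-based inclusive
convention of GFF3 appears only at the file boundary (and in text reports).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Iterator

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


class AnnotationError(ValueError):
    """Raised for structurally invalid annotation input."""


@dataclasses.dataclass(frozen=True)
class TranscriptAnnotation:
    """One transcript with a single ORF located on it.

    ``cds_start`` is the 0-based position of the first base of the start
    codon; ``cds_end`` is 0-based exclusive, one past the last base of the
    stop codon.  The CDS length is therefore ``cds_end - cds_start`` and is
    always a multiple of 3.
    """

    transcript_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise AnnotationError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"outside transcript of length {len(self.sequence)}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise AnnotationError(
                f"{self.transcript_id}: CDS length "
                f"{self.cds_end - self.cds_start} is not a multiple of 3"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def n_codons(self) -> int:
        """Number of codons in the CDS, including the stop codon."""
        return self.cds_length // 3

    @property
    def start_codon(self) -> str:
        return self.sequence[self.cds_start : self.cds_start + 3]

    @property
    def stop_codon(self) -> str:
        return self.sequence[self.cds_end - 3 : self.cds_end]

    def codon(self, index: int) -> str:
        """Codon ``index`` (0-based) of the CDS."""
        if not 0 <= index < self.n_codons:
            raise IndexError(f"codon index {index} out of range")
        p = self.cds_start + 3 * index
        return self.sequence[p : p + 3]


class AnnotationSet:
    """Ordered collection of :class:`TranscriptAnnotation`, keyed by id.

    Iteration follows FASTA input order.  Transcripts present in the FASTA
    but lacking a CDS feature are recorded in ``no_cds``; transcripts whose
    CDS failed validation are recorded in ``excluded`` with a reason.
    """

    def __init__(self, transcripts: Iterator[TranscriptAnnotation] = ()) -> None:
        self._transcripts: dict[str, TranscriptAnnotation] = {}
        self.no_cds: list[str] = []
        self.excluded: dict[str, str] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptAnnotation) -> None:
        if t.transcript_id in self._transcripts:
            raise AnnotationError(f"duplicate transcript id {t.transcript_id!r}")
        self._transcripts[t.transcript_id] = t

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptAnnotation]:
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptAnnotation:
        return self._transcripts[transcript_id]

    def ids(self) -> list[str]:
        return list(self._transcripts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return list(self) == list(other)


def _merged_cds_interval(
    features: list[tuple[int, int, str]], transcript_id: str
) -> tuple[int, int]:
    """Merge CDS lines (1-based inclusive) into one contiguous interval.

    Multiple CDS lines for one transcript are accepted only when contiguous;
    a gap means the GFF3 is genome-style (multi-exon), which is out of scope.
    """
    for _, _, strand in features:
        if strand == "-":
            raise AnnotationError(
                f"{transcript_id}: minus-strand CDS on a transcript; "
                "transcriptome FASTA is already spliced and plus-strand"
            )
    ivals = sorted((s, e) for s, e, _ in features)
    start, end = ivals[0]
    for s, e in ivals[1:]:
        if s != end + 1:
            raise AnnotationError(
                f"{transcript_id}: gapped CDS segments {ivals}; "
                "only contiguous transcript-space CDS is supported"
            )
        end = e
    return start, end


def load_annotation(
    fasta_path: str | Path,
    gff3_path: str | Path,
    on_invalid_cds: str = "warn",
) -> AnnotationSet:
    """Read FASTA + GFF3 into an :class:`AnnotationSet`.

    GFF3 1-based inclusive ``[start, end]`` is converted to 0-based half-open
    ``[start-1, end)``.  A CDS whose length is not a multiple of 3 is excluded
    with a warning by default (``on_invalid_cds="warn"``) because frame
    statistics are undefined for it; pass ``"error"`` to fail instead.
    """
    fasta_path, gff3_path = Path(fasta_path), Path(gff3_path)
    for p in (fasta_path, gff3_path):
        if not p.exists():
            raise FileNotFoundError(p)
    if on_invalid_cds not in ("warn", "error"):
        raise ValueError("on_invalid_cds must be 'warn' or 'error'")

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    seqs = {r.id: str(r.seq).upper() for r in records}
    if len(seqs) != len(records):
        raise AnnotationError("duplicate FASTA record ids")

    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    cds_by_seqid: dict[str, list[tuple[int, int, str]]] = {}
    for feat in db.features_of_type("CDS"):
        if feat.seqid not in seqs:
            raise AnnotationError(
                f"GFF3 seqid {feat.seqid!r} absent from FASTA"
            )
        cds_by_seqid.setdefault(feat.seqid, []).append(
            (feat.start, feat.end, feat.strand)
        )

    result = AnnotationSet()
    for rec in records:
        tid = rec.id
        if tid not in cds_by_seqid:
            result.no_cds.append(tid)
            continue
        start1, end1 = _merged_cds_interval(cds_by_seqid[tid], tid)
        cds_start, cds_end = start1 - 1, end1
        seq = seqs[tid]
        if cds_end > len(seq) or cds_start < 0:
            raise AnnotationError(
                f"{tid}: CDS {start1}..{end1} extends beyond transcript "
                f"length {len(seq)}"
            )
        if (cds_end - cds_start) % 3 != 0:
            msg = (
                f"{tid}: CDS length {cds_end - cds_start} not divisible by 3"
            )
            if on_invalid_cds == "error":
                raise AnnotationError(msg)
            warnings.warn(msg)
            result.excluded[tid] = "cds_length_not_multiple_of_3"
            continue
        result.add(TranscriptAnnotation(tid, seq, cds_start, cds_end))
    if result.no_cds:
        log.warning(
            "%d FASTA transcripts have no CDS feature: %s",
            len(result.no_cds), ", ".join(result.no_cds[:10]),
        )
    return result


def write_annotation(
    annotation: AnnotationSet, fasta_path: str | Path, gff3_path: str | Path
) -> None:
    """Write an AnnotationSet back to FASTA + GFF3 (roundtrip-exact)."""
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description="")
        for t in annotation
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in annotation:
            fh.write(
                "\t".join(
                    [
                        t.transcript_id, "ribogridkit", "CDS",
                        str(t.cds_start + 1), str(t.cds_end),
                        ".", "+", "0",
                        f"ID=CDS:{t.transcript_id};Name={t.transcript_id}",
                    ]
                )
                + "\n"
            )


def validate_annotation(
    annotation: AnnotationSet, check_codons: bool = True
) -> pd.DataFrame:
    """Per-transcript start/stop codon report (warnings only, nothing dropped).

    Non-ATG starts are biologically valid (e.g. near-cognate initiation), so
    failures are flagged, never fatal.
    """
    rows = []
    for t in annotation:
        start_ok = t.start_codon == START_CODON
        stop_ok = t.stop_codon in STOP_CODONS
        flags = []
        if check_codons:
            if not start_ok:
                flags.append("non_ATG_start")
            if not stop_ok:
                flags.append("no_stop_codon")
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "length": t.length,
                "cds_start_1based": t.cds_start + 1,
                "cds_end_1based": t.cds_end,
                "start_codon": t.start_codon,
                "stop_codon": t.stop_codon,
                "start_ok": start_ok,
                "stop_ok": stop_ok,
                "flags": ";".join(flags),
            }
        )
    cols = [
        "transcript_id", "length", "cds_start_1based", "cds_end_1based",
        "start_codon", "stop_codon", "start_ok", "stop_ok", "flags",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_validation_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)
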