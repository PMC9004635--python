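"""Pre-alignment read handling: demultiplexing and UMI extraction.

Multiplexed Ribo-seq libraries carry a sample barcode (and often a unique
molecular identifier, UMI) inside each read.  Demultiplexing assigns reads to
samples by Hamming distance to the barcode sheet; UMI extraction moves the
UMI bases out of the sequence and into the read identifier (underscore
suffix, the convention consumed by common deduplication tools).

A simple exact-match deduplication over (transcript, position, length, UMI)
is provided for aligned reads; network-based UMI collapsing is deliberately
left to dedicated tools.
"""

from __future__ import annotations

import dataclasses
import gzip
import logging
from collections import Counter
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd
import pysam

log = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class FastqRead:
    name: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise PreprocessError(
                f"{self.name}: sequence/quality length mismatch"
            )


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Iterate a FASTQ file (gzip-transparent)."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield FastqRead(entry.name, entry.sequence, entry.quality or "")


def _open_text(path: str | Path, mode: str = "wt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode.replace("t", ""))


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> int:
    n = 0
    with _open_text(path) as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")
            n += 1
    return n


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Demultiplexing


@dataclasses.dataclass(frozen=True)
class BarcodeSheet:
    """Sample -> barcode assignments with a shared mismatch budget."""

    entries: tuple[tuple[str, str], ...]
    max_mismatches: int = 1

    def __post_init__(self) -> None:
        if not self.entries:
            raise PreprocessError("empty barcode sheet")
        if self.max_mismatches < 0:
            raise PreprocessError("max_mismatches must be >= 0")
        names = [n for n, _ in self.entries]
        codes = [b.upper() for _, b in self.entries]
        if len(set(len(b) for b in codes)) != 1:
            raise PreprocessError("barcodes must all have equal length")
        if len(set(names)) != len(names):
            raise PreprocessError("duplicate sample names in barcode sheet")
        if len(set(codes)) != len(codes):
            raise PreprocessError("duplicate barcodes in barcode sheet")
        # Two barcodes closer than 2*max_mismatches can produce a read
        # strictly nearer the WRONG sample: reject the sheet outright.
        # At exactly 2*max_mismatches only equidistant ties are possible,
        # and ties go to Unassigned, so that separation is still usable.
        for i in range(len(codes)):
            for j in range(i + 1, len(codes)):
                d = hamming(codes[i], codes[j])
                if d < 2 * self.max_mismatches or d == 0:
                    raise PreprocessError(
                        f"barcodes {codes[i]} and {codes[j]} are only "
                        f"{d} mismatches apart (need >= "
                        f"{2 * self.max_mismatches} for safe assignment)"
                    )

    @property
    def barcode_length(self) -> int:
        return len(self.entries[0][1])

    @property
    def samples(self) -> list[str]:
        return [n for n, _ in self.entries]


def load_barcode_sheet(path: str | Path, max_mismatches: int = 1) -> BarcodeSheet:
    """Headerless 2-column TSV: sample name, barcode."""
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise PreprocessError(f"malformed barcode sheet line: {line!r}")
            entries.append((fields[0], fields[1].upper()))
    return BarcodeSheet(tuple(entries), max_mismatches)


UNASSIGNED = "Unassigned"


def assign_barcode(
    sequence: str, sheet: BarcodeSheet, offset: int = 0
) -> str | None:
    """Assign one read to a sample, or None for the Unassigned stream.

    The unique sample whose barcode is within ``max_mismatches`` wins; a tie
    at the minimal qualifying distance is conservatively unassigned.
    """
    L = sheet.barcode_length
    if offset + L > len(sequence):
        raise PreprocessError(
            f"read of length {len(sequence)} shorter than barcode region "
            f"[{offset}, {offset + L})"
        )
    observed = sequence[offset : offset + L].upper()
    best, best_d, tied = None, None, False
    for name, code in sheet.entries:
        d = hamming(observed, code)
        if best_d is None or d < best_d:
            best, best_d, tied = name, d, False
        elif d == best_d:
            tied = True
    if best_d is None or best_d > sheet.max_mismatches or tied:
        return None
    return best


def demultiplex(
    reads: Iterable[FastqRead],
    sheet: BarcodeSheet,
    outdir: str | Path | None = None,
    barcode_offset: int = 0,
) -> Counter:
    """Split a FASTQ stream by sample barcode.

    Returns per-sample read counts (including ``Unassigned``); conservation
    holds: the counts sum to the number of input reads.  When ``outdir`` is
    given, one FASTQ per sample plus ``Unassigned.fastq`` and a counts TSV
    are written there.
    """
    counts: Counter = Counter({name: 0 for name in sheet.samples})
    counts[UNASSIGNED] = 0
    writers: dict[str, IO[str]] = {}
    outdir_p = Path(outdir) if outdir is not None else None
    try:
        if outdir_p is not None:
            outdir_p.mkdir(parents=True, exist_ok=True)
            for name in sheet.samples + [UNASSIGNED]:
                writers[name] = _open_text(outdir_p / f"{name}.fastq")
        for read in reads:
            sample = assign_barcode(read.sequence, sheet, barcode_offset)
            key = sample if sample is not None else UNASSIGNED
            counts[key] += 1
            if writers:
                writers[key].write(
                    f"@{read.name}\n{read.sequence}\n+\n{read.quality}\n"
                )
    finally:
        for fh in writers.values():
            fh.close()
    if outdir_p is not None:
        pd.DataFrame(
            [(k, v) for k, v in counts.items()], columns=["sample", "n_reads"]
        ).to_csv(outdir_p / "demultiplex_counts.tsv", sep="\t", index=False)
    return counts


# ---------------------------------------------------------------------------
# UMI extraction


@dataclasses.dataclass(frozen=True)
class UmiSpec:
    """Where the UMI (and optional in-read barcode) sit in each read.

    Layout supported: [barcode][umi5]...insert...[umi3], with the barcode
    region given as (offset, length) in the raw read.
    """

    umi5_length: int = 0
    umi3_length: int = 0
    barcode_in_read: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.umi5_length < 0 or self.umi3_length < 0:
            raise PreprocessError("UMI lengths must be >= 0")
        if self.barcode_in_read is not None:
            off, L = self.barcode_in_read
            if off < 0 or L <= 0:
                raise PreprocessError("invalid barcode_in_read region")

    @property
    def removed_length(self) -> int:
        bc = self.barcode_in_read[1] if self.barcode_in_read else 0
        return self.umi5_length + self.umi3_length + bc


def extract_umi_read(read: FastqRead, spec: UmiSpec) -> FastqRead | None:
    """Process one read; returns None when the read is too short.

    The UMI bases are removed from sequence and quality in lockstep and the
    identifier gains the suffix ``_<umi5><umi3>``.  The in-read barcode, when
    configured, is removed as well (it carries no molecular information).
    """
    seq, qual = read.sequence, read.quality
    if spec.removed_length >= len(seq):
        return None
    if spec.barcode_in_read is not None:
        off, L = spec.barcode_in_read
        if off + L > len(seq):
            return None
        seq = seq[:off] + seq[off + L :]
        qual = qual[:off] + qual[off + L :]
    u5, u3 = spec.umi5_length, spec.umi3_length
    umi5 = seq[:u5]
    umi3 = seq[len(seq) - u3 :] if u3 else ""
    seq = seq[u5 : len(seq) - u3 or None]
    qual = qual[u5 : len(qual) - u3 or None]
    name = read.name
    if u5 or u3:
        name = f"{name}_{umi5}{umi3}"
    return FastqRead(name, seq, qual)


def extract_umi(
    reads: Iterable[FastqRead],
    spec: UmiSpec,
    out_path: str | Path | None = None,
    rejected_path: str | Path | None = None,
) -> tuple[list[FastqRead], list[FastqRead]]:
    """Apply :func:`extract_umi_read` to a stream.

    Too-short reads go to the rejected stream (never silently dropped).
    Returns (accepted, rejected); also writes FASTQ files when paths given.
    """
    accepted: list[FastqRead] = []
    rejected: list[FastqRead] = []
    for read in reads:
        out = extract_umi_read(read, spec)
        if out is None:
            rejected.append(read)
        else:
            accepted.append(out)
    if out_path is not None:
        write_fastq(accepted, out_path)
    if rejected_path is not None:
        write_fastq(rejected, rejected_path)
    return accepted, rejected


# ---------------------------------------------------------------------------
# Exact-match UMI deduplication on aligned reads


def umi_of(query_name: str) -> str:
    """UMI from an underscore-suffixed read identifier."""
    if "_" not in query_name:
        raise PreprocessError(
            f"read {query_name!r} lacks a _UMI identifier suffix"
        )
    return query_name.rsplit("_", 1)[1]


def dedup_exact(
    in_bam: str | Path, out_bam: str | Path
) -> tuple[int, int]:
    """Keep one alignment per (transcript, 5' position, length, UMI).

    Input must be sorted by transcript then position; among exact duplicates
    the first in sort order survives.  Returns (n_kept, n_removed).
    """
    kept = removed = 0
    with pysam.AlignmentFile(str(in_bam), "rb", check_sq=False) as bam:
        with pysam.AlignmentFile(str(out_bam), "wb", template=bam) as out:
            seen: set[tuple] = set()
            for rec in bam.fetch(until_eof=True):
                key = (
                    rec.reference_id,
                    rec.reference_start,
                    rec.query_alignment_length,
                    umi_of(rec.query_name),
                )
                if key in seen:
                    removed += 1
                    continue
                seen.add(key)
                out.write(rec)
                kept += 1
    log.info("dedup_exact: kept %d, removed %d duplicates", kept, removed)
    return kept, removed
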