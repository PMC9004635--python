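"""Post-alignment footprint handling on transcriptome BAMs.

Two steps sit between the aligner and the count matrices:

* ``trim_5p_mismatch`` removes non-templated bases that some (notably viral)
  reverse transcriptases append to cDNA 5' ends.  These appear after
  alignment as a run of mismatches anchored at read offset 0 and, left in
  place, shift the apparent 5' position and corrupt reading-frame
  statistics.  Only a terminal mismatch run is ever trimmed; an isolated
  internal mismatch is sequencing error or a variant, not evidence of
  non-templated addition.

* ``filter_alignments`` selects the primary, mapped, plus-strand alignments
  within the configured length bounds — the reads that populate the
  ribogrid — and accounts for every rejected record by reason.

Mismatch positions are taken from the MD tag, so no reference FASTA is
needed at this stage.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam

from .annotation import AnnotationSet

log = logging.getLogger(__name__)

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


class PostprocessError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class AlignedFootprint:
    """A footprint alignment reduced to what the ribogrid needs.

    ``read_length`` counts aligned bases only (soft clips excluded); for the
    ungapped alignments handled here ``pos3 == pos5 + read_length - 1``.
    """

    transcript_id: str
    pos5: int
    read_length: int
    is_primary: bool = True
    mismatch_positions: tuple[int, ...] = ()

    @property
    def pos3(self) -> int:
        return self.pos5 + self.read_length - 1


def expand_md(md: str) -> list[str | None]:
    """Expand an MD tag into one entry per aligned reference base.

    Entries are None for a match and the reference base for a mismatch.
    Deletions (``^``) are not supported — footprint alignments are ungapped.
    """
    out: list[str | None] = []
    for m in _MD_TOKEN.finditer(md):
        num, deletion, base = m.groups()
        if num is not None:
            out.extend([None] * int(num))
        elif deletion is not None:
            raise PostprocessError(f"MD tag {md!r} contains a deletion")
        else:
            out.append(base.upper())
    return out


def encode_md(entries: list[str | None]) -> str:
    """Inverse of :func:`expand_md` (canonical form: digits between bases)."""
    parts: list[str] = []
    run = 0
    for e in entries:
        if e is None:
            run += 1
        else:
            parts.append(str(run))
            parts.append(e)
            run = 0
    parts.append(str(run))
    return "".join(parts)


@dataclasses.dataclass
class TrimSummary:
    """Counts of records trimmed by 0..max_trim bases, rejected, passed through."""

    max_trim: int
    n_trimmed: Counter = dataclasses.field(default_factory=Counter)
    n_rejected: int = 0
    n_passthrough: int = 0

    @property
    def n_total(self) -> int:
        return sum(self.n_trimmed.values()) + self.n_rejected + self.n_passthrough

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": f"trimmed_{k}", "n": self.n_trimmed.get(k, 0)}
            for k in range(self.max_trim + 1)
        ]
        rows.append({"category": "rejected", "n": self.n_rejected})
        rows.append({"category": "passthrough", "n": self.n_passthrough})
        return pd.DataFrame(rows)


def leading_mismatch_run(rec: pysam.AlignedSegment) -> int:
    """Length of the consecutive mismatch run starting at read offset 0."""
    entries = expand_md(str(rec.get_tag("MD")))
    k = 0
    for e in entries:
        if e is None:
            break
        k += 1
    return k


def trim_5p_mismatch(
    rec: pysam.AlignedSegment, max_trim: int = 2
) -> tuple[str, int]:
    """Trim the 5'-terminal mismatch run off one record, in place.

    Returns ``(status, k)`` where status is ``"trimmed"`` (k bases removed,
    possibly 0), ``"rejected"`` (k exceeded ``max_trim``; record should go to
    the discard stream) or ``"passthrough"`` (gapped/clipped 5' terminus —
    left untouched, counted).  The record's POS, CIGAR, MD and NM are
    rewritten consistently so that re-deriving mismatches afterwards shows
    none at offset 0; the operation is idempotent.
    """
    if rec.is_unmapped or rec.is_reverse:
        return "passthrough", 0
    if not rec.has_tag("MD"):
        raise PostprocessError(
            f"{rec.query_name}: no MD tag and no reference available"
        )
    cig = rec.cigartuples or []
    # Only a plain fully-aligned read (single M op) has an unambiguous
    # 5' terminus; anything gapped or clipped there is passed through.
    if len(cig) != 1 or cig[0][0] != 0:
        return "passthrough", 0
    entries = expand_md(str(rec.get_tag("MD")))
    k = 0
    for e in entries:
        if e is None:
            break
        k += 1
    if k > max_trim:
        return "rejected", k
    if k > 0:
        seq = rec.query_sequence[k:]
        qual = rec.query_qualities[k:] if rec.query_qualities is not None else None
        nm = int(rec.get_tag("NM")) - k if rec.has_tag("NM") else None
        rec.reference_start += k
        rec.cigartuples = [(0, len(seq))]
        rec.query_sequence = seq  # resets qualities
        rec.query_qualities = qual
        rec.set_tag("MD", encode_md(entries[k:]))
        if nm is not None:
            rec.set_tag("NM", nm)
    return "trimmed", k


def trim_bam(
    in_bam: str | Path,
    out_bam: str | Path,
    discarded_bam: str | Path | None = None,
    max_trim: int = 2,
) -> TrimSummary:
    """Apply :func:`trim_5p_mismatch` to a whole BAM.

    Conservation: every input record lands in exactly one of the output
    stream, the discard stream, or the pass-through tally (pass-throughs are
    written to the output stream untrimmed).
    """
    summary = TrimSummary(max_trim=max_trim)
    with pysam.AlignmentFile(str(in_bam), "rb", check_sq=False) as bam:
        out = pysam.AlignmentFile(str(out_bam), "wb", template=bam)
        disc = (
            pysam.AlignmentFile(str(discarded_bam), "wb", template=bam)
            if discarded_bam is not None
            else None
        )
        try:
            for rec in bam.fetch(until_eof=True):
                status, k = trim_5p_mismatch(rec, max_trim)
                if status == "rejected":
                    summary.n_rejected += 1
                    if disc is not None:
                        disc.write(rec)
                elif status == "passthrough":
                    summary.n_passthrough += 1
                    out.write(rec)
                else:
                    summary.n_trimmed[k] += 1
                    out.write(rec)
        finally:
            out.close()
            if disc is not None:
                disc.close()
    return summary


@dataclasses.dataclass
class FilterReport:
    n_accepted: int = 0
    reasons: Counter = dataclasses.field(default_factory=Counter)

    @property
    def n_total(self) -> int:
        return self.n_accepted + sum(self.reasons.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"category": "accepted", "n": self.n_accepted}]
        for reason in ("unmapped", "secondary", "supplementary",
                       "minus_strand", "too_short", "too_long"):
            rows.append({"category": reason, "n": self.reasons.get(reason, 0)})
        return pd.DataFrame(rows)


def _record_mismatches(rec: pysam.AlignedSegment) -> tuple[int, ...]:
    if not rec.has_tag("MD"):
        return ()
    return tuple(
        i for i, e in enumerate(expand_md(str(rec.get_tag("MD"))))
        if e is not None
    )


def iter_footprints(
    bam: str | Path | Iterable[pysam.AlignedSegment],
    annotation: AnnotationSet | None = None,
    min_length: int = 10,
    max_length: int = 50,
    report: FilterReport | None = None,
) -> Iterator[AlignedFootprint]:
    """Yield accepted footprints from a transcriptome BAM, tallying rejects.

    Keeps primary, mapped, plus-strand alignments whose aligned length lies
    in ``[min_length, max_length]``.  Pass a :class:`FilterReport` to collect
    the per-reason rejection counts (filled as the stream is consumed).
    """
    own_handle = isinstance(bam, (str, Path))
    handle = (
        pysam.AlignmentFile(str(bam), "rb", check_sq=False) if own_handle else None
    )
    records = handle.fetch(until_eof=True) if handle is not None else bam
    if annotation is not None and handle is not None:
        missing = [r for r in handle.references if r not in annotation]
        if missing:
            handle.close()
            raise PostprocessError(
                "BAM references absent from annotation: "
                + ", ".join(missing[:10])
            )
    try:
        for rec in records:
            if rec.is_unmapped:
                if report:
                    report.reasons["unmapped"] += 1
                continue
            if rec.is_secondary:
                if report:
                    report.reasons["secondary"] += 1
                continue
            if rec.is_supplementary:
                if report:
                    report.reasons["supplementary"] += 1
                continue
            if rec.is_reverse:
                if report:
                    report.reasons["minus_strand"] += 1
                continue
            length = rec.query_alignment_length
            if length < min_length:
                if report:
                    report.reasons["too_short"] += 1
                continue
            if length > max_length:
                if report:
                    report.reasons["too_long"] += 1
                continue
            tid = rec.reference_name
            if annotation is not None and tid not in annotation:
                raise PostprocessError(
                    f"BAM reference {tid!r} absent from annotation"
                )
            if report:
                report.n_accepted += 1
            yield AlignedFootprint(
                transcript_id=tid,
                pos5=rec.reference_start,
                read_length=length,
                is_primary=True,
                mismatch_positions=_record_mismatches(rec),
            )
    finally:
        if handle is not None:
            handle.close()


def filter_alignments(
    bam: str | Path,
    annotation: AnnotationSet | None = None,
    min_length: int = 10,
    max_length: int = 50,
) -> tuple[list[AlignedFootprint], FilterReport]:
    """Materialized form of :func:`iter_footprints` with its filter report."""
    report = FilterReport()
    footprints = list(
        iter_footprints(bam, annotation, min_length, max_length, report)
    )
    return footprints, report
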