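"""A-site assignment: from footprint (length, 5' position) to the decoded codon.

A ribosome protects ~28 nt of mRNA, and the codon in its A site (the one
being decoded) sits at a fixed displacement from a read end that depends on
read length and on the organism's digestion chemistry: eukaryotic protocols
anchor at the 5' end, bacterial ones at the 3' end.  The displacement table
is user-supplied, one entry per read length; lengths absent from the table
contribute no A-site assignment.

Convention (documented, load-bearing): the assigned position is the FIRST
nucleotide of the A-site codon, so the codon index within the CDS is
``(a - cds_start) // 3``.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .annotation import TranscriptAnnotation
from .grid import Ribogrid
from .postprocess import AlignedFootprint

Anchor = Literal["five_prime", "three_prime"]


class AsiteError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class AsiteOffsetTable:
    """Read-length -> displacement map, anchored at one read end."""

    anchor: Anchor
    offsets: dict[int, int]

    def __post_init__(self) -> None:
        if self.anchor not in ("five_prime", "three_prime"):
            raise AsiteError(f"unknown anchor {self.anchor!r}")
        for length, d in self.offsets.items():
            if not 0 <= d < length:
                raise AsiteError(
                    f"displacement {d} invalid for read length {length}"
                )

    def to_dual(self) -> "AsiteOffsetTable":
        """The equivalent table anchored at the other read end.

        For a read of length l, a 5'-anchored displacement d addresses the
        same nucleotide as a 3'-anchored displacement l - 1 - d.
        """
        other: Anchor = (
            "three_prime" if self.anchor == "five_prime" else "five_prime"
        )
        return AsiteOffsetTable(
            other, {l: l - 1 - d for l, d in self.offsets.items()}
        )


#: Standard yeast-style 5'-anchored displacements (28-mers offset by 15 nt).
EUKARYOTE_PRESET = AsiteOffsetTable(
    "five_prime",
    {26: 14, 27: 14, 28: 15, 29: 15, 30: 15, 31: 16, 32: 16},
)


def load_offsets(path: str | Path, anchor: Anchor = "five_prime") -> AsiteOffsetTable:
    """Read a displacement TSV with header ``read_length<TAB>offset``."""
    df = pd.read_csv(path, sep="\t")
    required = {"read_length", "offset"}
    if not required.issubset(df.columns):
        raise AsiteError(
            f"offset table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return AsiteOffsetTable(
        anchor, dict(zip(df["read_length"].astype(int), df["offset"].astype(int)))
    )


def write_offsets(table: AsiteOffsetTable, path: str | Path) -> None:
    pd.DataFrame(
        sorted(table.offsets.items()), columns=["read_length", "offset"]
    ).to_csv(path, sep="\t", index=False)


def asite_position(
    pos5: int,
    length: int,
    table: AsiteOffsetTable,
    transcript_length: int | None = None,
) -> int | None:
    """A-site nucleotide for a footprint, or None when unassignable.

    5'-anchored: ``pos5 + offset``; 3'-anchored: ``(pos5 + length - 1) -
    offset``.  Returns None for lengths absent from the table or (when
    ``transcript_length`` is given) positions outside the transcript.
    """
    if length not in table.offsets:
        return None
    d = table.offsets[length]
    if table.anchor == "five_prime":
        a = pos5 + d
    else:
        a = (pos5 + length - 1) - d
    if a < 0:
        return None
    if transcript_length is not None and a >= transcript_length:
        return None
    return a


def frame_of_position(a: int, cds_start: int) -> int:
    """Reading frame in {0, 1, 2} of position ``a`` relative to the start codon.

    Uses the mathematical modulus, so positions upstream of the start codon
    also land in {0, 1, 2} (e.g. one base upstream is frame 2).
    """
    return (a - cds_start) % 3


@dataclasses.dataclass
class CodonDensity:
    """A-site-assigned footprint counts per CDS codon (stop codon included)."""

    transcript_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise AsiteError("negative codon density")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodonDensity):
            return NotImplemented
        return self.transcript_id == other.transcript_id and np.array_equal(
            self.counts, other.counts
        )


#: Exclusion reasons tallied by the codon-density builders.
EXCLUSION_REASONS = ("unlisted_length", "out_of_transcript", "outside_cds")


def _classify(
    a: int | None, annot: TranscriptAnnotation
) -> tuple[int | None, str | None]:
    """(codon index, None) for an in-CDS A-site, else (None, reason)."""
    if a is None:
        return None, "out_of_transcript"
    if not annot.cds_start <= a < annot.cds_end:
        return None, "outside_cds"
    return (a - annot.cds_start) // 3, None


def codon_density_from_grid(
    grid: Ribogrid,
    annot: TranscriptAnnotation,
    table: AsiteOffsetTable,
) -> tuple[CodonDensity, Counter]:
    """Codon-level density from a ribogrid, with exclusions tallied by reason.

    Conservation: ``density.total + sum(exclusions.values()) == grid.total``.
    """
    if grid.transcript_id != annot.transcript_id:
        raise AsiteError(
            f"grid {grid.transcript_id!r} vs annotation "
            f"{annot.transcript_id!r} mismatch"
        )
    counts = np.zeros(annot.n_codons, dtype=np.int64)
    exclusions: Counter = Counter()
    rows, cols = np.nonzero(grid.counts)
    for r, p in zip(rows, cols):
        n = int(grid.counts[r, p])
        length = grid.min_length + int(r)
        if length not in table.offsets:
            exclusions["unlisted_length"] += n
            continue
        a = asite_position(int(p), length, table, annot.length)
        codon, reason = _classify(a, annot)
        if codon is None:
            exclusions[reason] += n
        else:
            counts[codon] += n
    return CodonDensity(annot.transcript_id, counts), exclusions


def codon_density_from_footprints(
    footprints: Iterable[AlignedFootprint],
    annot: TranscriptAnnotation,
    table: AsiteOffsetTable,
) -> tuple[CodonDensity, Counter]:
    """Codon density straight from the footprint stream (no grid).

    Exists to demonstrate that the ribogrid is a sufficient statistic: this
    brute-force route and :func:`codon_density_from_grid` must agree exactly.
    """
    counts = np.zeros(annot.n_codons, dtype=np.int64)
    exclusions: Counter = Counter()
    for fp in footprints:
        if fp.transcript_id != annot.transcript_id:
            continue
        if fp.read_length not in table.offsets:
            exclusions["unlisted_length"] += 1
            continue
        a = asite_position(fp.pos5, fp.read_length, table, annot.length)
        codon, reason = _classify(a, annot)
        if codon is None:
            exclusions[reason] += 1
        else:
            counts[codon] += 1
    return CodonDensity(annot.transcript_id, counts), exclusions


def write_codon_density_tsv(
    densities: dict[str, CodonDensity], path: str | Path
) -> None:
    rows = []
    for tid, d in densities.items():
        for c, n in enumerate(d.counts):
            rows.append({"transcript_id": tid, "codon_index": c, "count": int(n)})
    pd.DataFrame(rows, columns=["transcript_id", "codon_index", "count"]).to_csv(
        path, sep="\t", index=False
    )


def write_exclusion_report_tsv(
    exclusions: dict[str, Counter], path: str | Path
) -> None:
    rows = []
    for tid, exc in exclusions.items():
        row = {"transcript_id": tid}
        for reason in EXCLUSION_REASONS:
            row[reason] = exc.get(reason, 0)
        rows.append(row)
    pd.DataFrame(rows, columns=["transcript_id", *EXCLUSION_REASONS]).to_csv(
        path, sep="\t", index=False
    )
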