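"""The ribogrid: per-transcript footprint count matrices in HDF5.

A ribogrid stores, for one transcript, an integer matrix with one row per
read length (``min_length .. max_length``) and one column per 0-based 5'-end
position.  Together with the annotation these counts are a sufficient
statistic for the downstream analyses — frame proportions, metagene
profiles and codon densities all derive from them without returning to the
raw alignments.

H5 schema (this package's documented dialect)
---------------------------------------------
root attributes:   ``schema_version``, ``sample_name``, ``min_length``,
                   ``max_length``, plus optional provenance
                   (``tool_version``, ``source_bam``, ``created``)
one group per transcript, named by transcript id, containing
  dataset ``reads``  — 2-D integer, rows = read lengths min..max ascending,
                       columns = 0-based 5' positions
  attributes         ``transcript_length``, ``cds_start``, ``cds_end``
                       (0-based half-open)

Datasets are chunked and gzip-compressed; compression is lossless so the
write -> read roundtrip is bit-exact.  Groups are created with order
tracking so iteration order survives the roundtrip.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .annotation import AnnotationSet
from .postprocess import AlignedFootprint

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

DEFAULT_MIN_LENGTH = 10
DEFAULT_MAX_LENGTH = 50


class RibogridError(ValueError):
    pass


class RibogridSchemaError(RibogridError):
    """The H5 file does not conform to the documented ribogrid schema."""


@dataclasses.dataclass
class Ribogrid:
    """Footprint counts for one transcript by (read length, 5' position)."""

    transcript_id: str
    min_length: int
    max_length: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise RibogridError("ribogrid counts must be integral")
        n_lengths = self.max_length - self.min_length + 1
        if self.counts.ndim != 2 or self.counts.shape[0] != n_lengths:
            raise RibogridError(
                f"{self.transcript_id}: counts shape {self.counts.shape} "
                f"does not match length bounds "
                f"[{self.min_length}, {self.max_length}]"
            )
        if (self.counts < 0).any():
            raise RibogridError("negative ribogrid count")

    @classmethod
    def zeros(
        cls, transcript_id: str, transcript_length: int,
        min_length: int, max_length: int,
    ) -> "Ribogrid":
        shape = (max_length - min_length + 1, transcript_length)
        return cls(transcript_id, min_length, max_length,
                   np.zeros(shape, dtype=np.int64))

    @property
    def transcript_length(self) -> int:
        return self.counts.shape[1]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def increment(self, read_length: int, pos5: int, n: int = 1) -> None:
        if not self.min_length <= read_length <= self.max_length:
            raise RibogridError(
                f"read length {read_length} outside grid bounds "
                f"[{self.min_length}, {self.max_length}]"
            )
        if not 0 <= pos5 < self.transcript_length:
            raise RibogridError(
                f"5' position {pos5} outside transcript "
                f"{self.transcript_id} (length {self.transcript_length})"
            )
        if pos5 + read_length > self.transcript_length:
            raise RibogridError(
                f"footprint (length {read_length}, 5' {pos5}) overhangs the "
                f"3' end of {self.transcript_id}"
            )
        self.counts[read_length - self.min_length, pos5] += n

    def slice(
        self,
        length_range: tuple[int, int],
        position_window: tuple[int, int],
    ) -> np.ndarray:
        """Sub-matrix for inclusive length and position ranges."""
        l1, l2 = length_range
        p1, p2 = position_window
        if l1 > l2 or p1 > p2:
            raise RibogridError("inverted slice range")
        if not (self.min_length <= l1 and l2 <= self.max_length):
            raise RibogridError("length range outside grid bounds")
        if not (0 <= p1 and p2 < self.transcript_length):
            raise RibogridError("position window outside transcript")
        return self.counts[
            l1 - self.min_length : l2 - self.min_length + 1, p1 : p2 + 1
        ]

    def by_length(self) -> dict[int, int]:
        """Row sums: footprint count per read length (nonzero rows only)."""
        sums = self.counts.sum(axis=1)
        return {
            self.min_length + i: int(s) for i, s in enumerate(sums) if s > 0
        }

    def by_length_full(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def by_position(self) -> np.ndarray:
        """Column sums: footprint count per 5' position."""
        return self.counts.sum(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ribogrid):
            return NotImplemented
        return (
            self.transcript_id == other.transcript_id
            and self.min_length == other.min_length
            and self.max_length == other.max_length
            and np.array_equal(self.counts, other.counts)
        )


def build_ribogrid(
    footprints: Iterable[AlignedFootprint],
    annotation: AnnotationSet,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_length: int = DEFAULT_MAX_LENGTH,
    include_empty: bool = True,
) -> dict[str, Ribogrid]:
    """Tally filtered footprints into one grid per transcript.

    Each footprint increments exactly one cell, so the total over all grids
    equals the number of input footprints.  ``include_empty`` keeps explicit
    zero grids for transcripts without footprints so downstream gene tables
    contain explicit zeros (count-matrix consumers need all genes).
    """
    if min_length > max_length:
        raise RibogridError("min_length > max_length")
    grids: dict[str, Ribogrid] = {}
    if include_empty:
        for t in annotation:
            grids[t.transcript_id] = Ribogrid.zeros(
                t.transcript_id, t.length, min_length, max_length
            )
    for fp in footprints:
        if fp.transcript_id not in annotation:
            raise RibogridError(
                f"footprint transcript {fp.transcript_id!r} not in annotation"
            )
        if not min_length <= fp.read_length <= max_length:
            raise RibogridError(
                f"footprint length {fp.read_length} outside "
                f"[{min_length}, {max_length}]: filtering contract violated"
            )
        if fp.transcript_id not in grids:
            grids[fp.transcript_id] = Ribogrid.zeros(
                fp.transcript_id,
                annotation[fp.transcript_id].length,
                min_length,
                max_length,
            )
        grids[fp.transcript_id].increment(fp.read_length, fp.pos5)
    return grids


def total_counts(grids: Mapping[str, Ribogrid]) -> int:
    return sum(g.total for g in grids.values())


_REQUIRED_ROOT_ATTRS = ("schema_version", "sample_name", "min_length", "max_length")
_REQUIRED_GROUP_ATTRS = ("transcript_length", "cds_start", "cds_end")


def write_ribogrid_h5(
    grids: Mapping[str, Ribogrid],
    annotation: AnnotationSet,
    path: str | Path,
    sample_name: str = "sample",
    source_bam: str | None = None,
    timestamp: str | None = None,
) -> Path:
    """Serialize grids to the documented H5 schema.

    ``timestamp`` is injected by the caller; when None the attribute is
    omitted so identical inputs produce byte-identical files.
    """
    if not grids:
        raise RibogridError("refusing to write an empty ribogrid file")
    bounds = {(g.min_length, g.max_length) for g in grids.values()}
    if len(bounds) != 1:
        raise RibogridError(f"mixed length bounds across grids: {bounds}")
    (min_length, max_length) = next(iter(bounds))
    path = Path(path)
    with h5py.File(path, "w", track_order=True) as h5:
        h5.attrs["schema_version"] = SCHEMA_VERSION
        h5.attrs["sample_name"] = sample_name
        h5.attrs["min_length"] = min_length
        h5.attrs["max_length"] = max_length
        h5.attrs["tool_version"] = __version__
        if source_bam is not None:
            h5.attrs["source_bam"] = source_bam
        if timestamp is not None:
            h5.attrs["created"] = timestamp
        for tid, grid in grids.items():
            ann = annotation[tid]
            grp = h5.create_group(tid, track_order=True)
            grp.attrs["transcript_length"] = ann.length
            grp.attrs["cds_start"] = ann.cds_start
            grp.attrs["cds_end"] = ann.cds_end
            grp.create_dataset(
                "reads",
                data=grid.counts.astype(np.int64),
                chunks=True,
                compression="gzip",
                shuffle=True,
            )
    return path


def read_ribogrid_h5(
    path: str | Path,
) -> tuple[dict[str, Ribogrid], dict[str, object]]:
    """Load a ribogrid file, validating the schema.

    Returns (grids in stored order, root attributes incl. per-transcript
    CDS coordinates under ``cds``).
    """
    path = Path(path)
    grids: dict[str, Ribogrid] = {}
    with h5py.File(path, "r") as h5:
        for attr in _REQUIRED_ROOT_ATTRS:
            if attr not in h5.attrs:
                raise RibogridSchemaError(
                    f"{path}: missing required root attribute {attr!r}"
                )
        version = str(h5.attrs["schema_version"])
        if version != SCHEMA_VERSION:
            raise RibogridSchemaError(
                f"{path}: schema version {version!r} != {SCHEMA_VERSION!r}"
            )
        min_length = int(h5.attrs["min_length"])
        max_length = int(h5.attrs["max_length"])
        meta: dict[str, object] = {
            k: (v.item() if isinstance(v, np.generic) else str(v))
            for k, v in h5.attrs.items()
        }
        cds: dict[str, tuple[int, int, int]] = {}
        for tid in h5.keys():
            grp = h5[tid]
            for attr in _REQUIRED_GROUP_ATTRS:
                if attr not in grp.attrs:
                    raise RibogridSchemaError(
                        f"{path}:/{tid}: missing required attribute {attr!r}"
                    )
            if "reads" not in grp:
                raise RibogridSchemaError(
                    f"{path}:/{tid}: missing 'reads' dataset"
                )
            data = grp["reads"][()]
            if not np.issubdtype(data.dtype, np.integer):
                raise RibogridSchemaError(
                    f"{path}:/{tid}: 'reads' dataset is not integer-typed"
                )
            grids[tid] = Ribogrid(tid, min_length, max_length, data)
            cds[tid] = (
                int(grp.attrs["transcript_length"]),
                int(grp.attrs["cds_start"]),
                int(grp.attrs["cds_end"]),
            )
        meta["cds"] = cds
    return grids, meta


def write_length_counts_tsv(
    grids: Mapping[str, Ribogrid], path: str | Path
) -> pd.DataFrame:
    """Per-length footprint counts in text form (read_length, n_reads)."""
    bounds = {(g.min_length, g.max_length) for g in grids.values()}
    if len(bounds) != 1:
        raise RibogridError("mixed length bounds across grids")
    min_length, max_length = next(iter(bounds))
    totals = np.zeros(max_length - min_length + 1, dtype=np.int64)
    for g in grids.values():
        totals += g.by_length_full()
    df = pd.DataFrame(
        {"read_length": np.arange(min_length, max_length + 1), "n_reads": totals}
    )
    df.to_csv(path, sep="\t", index=False)
    return df
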