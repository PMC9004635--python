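"""Sample- and gene-level Ribo-seq quantifications.

Everything here consumes ribogrids plus annotation (and an A-site
displacement table where codon resolution is needed):

* read-length distribution;
* per-gene reading-frame proportions — elongating ribosomes step one codon
  at a time, so a good library concentrates A-sites in frame 0;
* metagene profiles around the start (or stop) codon, whose period-3
  oscillation is the classic footprinting signature, made assertable by a
  spectral periodicity score;
* gene-level counts, per-codon density and TPM (transcripts per million);
* codon-specific density versus an external per-codon feature such as tRNA
  gene copy number, summarized by a permutation-tested Spearman correlation.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import STOP_CODONS, AnnotationSet
from .asite import (
    AsiteOffsetTable,
    CodonDensity,
    asite_position,
    codon_density_from_grid,
    frame_of_position,
)
from .grid import Ribogrid

log = logging.getLogger(__name__)

DEFAULT_MIN_READS = 64
DEFAULT_METAGENE_WINDOW = 25

#: The 61 sense codons (4^3 minus the three stops), fixed order.
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


class SummaryError(ValueError):
    pass


def _common_bounds(grids: Mapping[str, Ribogrid]) -> tuple[int, int]:
    bounds = {(g.min_length, g.max_length) for g in grids.values()}
    if len(bounds) != 1:
        raise SummaryError(f"mixed length bounds across grids: {bounds}")
    return next(iter(bounds))


def length_distribution(grids: Mapping[str, Ribogrid]) -> pd.Series:
    """Footprint counts per read length, summed over transcripts."""
    min_length, max_length = _common_bounds(grids)
    totals = np.zeros(max_length - min_length + 1, dtype=np.int64)
    for g in grids.values():
        totals += g.by_length_full()
    return pd.Series(
        totals, index=pd.RangeIndex(min_length, max_length + 1, name="read_length"),
        name="n_reads",
    )


# ---------------------------------------------------------------------------
# Reading-frame proportions

FrameFrom = Literal["asite", "pos5"]


def frame_counts_for_grid(
    grid: Ribogrid,
    annot,
    table: AsiteOffsetTable,
    frame_from: FrameFrom = "asite",
) -> np.ndarray:
    """CDS-assigned footprint counts by reading frame (length-3 vector).

    ``frame_from="asite"`` takes the frame of the displaced A-site position
    (the analytical default); ``"pos5"`` takes the raw 5'-end frame, the view
    in which untrimmed non-templated 5' additions visibly distort frame
    statistics.  In both modes only footprints whose A-site lies in the CDS
    are counted, so the two modes tally the same read set.
    """
    counts = np.zeros(3, dtype=np.int64)
    rows, cols = np.nonzero(grid.counts)
    for r, p in zip(rows, cols):
        n = int(grid.counts[r, p])
        length = grid.min_length + int(r)
        if length not in table.offsets:
            continue
        a = asite_position(int(p), length, table, annot.length)
        if a is None or not annot.cds_start <= a < annot.cds_end:
            continue
        pos = a if frame_from == "asite" else int(p)
        counts[frame_of_position(pos, annot.cds_start)] += n
    return counts


def frame_proportions_per_gene(
    grids: Mapping[str, Ribogrid],
    annotation: AnnotationSet,
    table: AsiteOffsetTable,
    min_reads: int = DEFAULT_MIN_READS,
    frame_from: FrameFrom = "asite",
) -> pd.DataFrame:
    """Per-transcript frame counts and proportions.

    Transcripts with fewer than ``min_reads`` CDS-assigned footprints are
    flagged ``low_coverage`` (their proportions are noise, not signal); a
    zero-count transcript has NaN proportions rather than a division error.
    """
    rows = []
    for tid, grid in grids.items():
        annot = annotation[tid]
        n = frame_counts_for_grid(grid, annot, table, frame_from)
        total = int(n.sum())
        props = (n / total) if total > 0 else np.full(3, np.nan)
        rows.append(
            {
                "transcript_id": tid,
                "n_frame0": int(n[0]),
                "n_frame1": int(n[1]),
                "n_frame2": int(n[2]),
                "n_total": total,
                "p0": props[0],
                "p1": props[1],
                "p2": props[2],
                "low_coverage": total < min_reads,
            }
        )
    return pd.DataFrame(rows)


def pooled_frame_proportions(frame_table: pd.DataFrame) -> np.ndarray:
    """Sample-level frame proportions pooled over all genes."""
    n = frame_table[["n_frame0", "n_frame1", "n_frame2"]].sum().to_numpy(float)
    total = n.sum()
    if total == 0:
        return np.full(3, np.nan)
    return n / total


# ---------------------------------------------------------------------------
# Metagene profile and periodicity

MetageneAnchor = Literal["start_codon", "stop_codon"]


@dataclasses.dataclass
class MetageneProfile:
    """Counts at positions relative to a common anchor, pooled over genes.

    ``rel_positions`` spans ``[-3*window, 3*window)`` (half-open, length a
    multiple of 3 so the periodicity spectrum has an exact period-3 bin).
    ``n_transcripts[i]`` counts transcripts whose coordinates cover relative
    position i, for per-position normalization.
    """

    anchor: MetageneAnchor
    rel_positions: np.ndarray
    counts: np.ndarray
    n_transcripts: np.ndarray
    by_length: dict[int, np.ndarray] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rel_position": self.rel_positions,
                "count": self.counts,
                "n_transcripts": self.n_transcripts,
            }
        )

    def downstream_counts(self) -> np.ndarray:
        """Counts at relative positions >= 0 (inside the CDS for a start
        anchor).  Scoring periodicity on this segment avoids the spectral
        leakage of the coverage step at the anchor, which otherwise
        dominates the low-frequency bins."""
        return self.counts[len(self.counts) // 2 :]


def metagene_profile(
    grids: Mapping[str, Ribogrid],
    annotation: AnnotationSet,
    anchor: MetageneAnchor = "start_codon",
    window_codons: int = DEFAULT_METAGENE_WINDOW,
    table: AsiteOffsetTable | None = None,
    use_asite: bool = False,
    length_stratified: bool = False,
) -> MetageneProfile:
    """Pool footprint 5'-end (or A-site) counts around the anchor codon.

    The anchor position is the first nucleotide of the start codon
    (``cds_start``) or of the stop codon (``cds_end - 3``).  By default the
    raw 5' ends are counted — the diagnostic view in which the
    length-dependent displacement is visible; ``use_asite=True`` counts
    displaced A-site positions instead (requires ``table``).
    """
    if window_codons < 1:
        raise SummaryError("window_codons must be >= 1")
    if use_asite and table is None:
        raise SummaryError("use_asite=True requires an offset table")
    w = 3 * window_codons
    rel = np.arange(-w, w)
    counts = np.zeros(2 * w, dtype=np.int64)
    n_tx = np.zeros(2 * w, dtype=np.int64)
    strat: dict[int, np.ndarray] = {}
    for tid, grid in grids.items():
        annot = annotation[tid]
        anchor_pos = (
            annot.cds_start if anchor == "start_codon" else annot.cds_end - 3
        )
        lo = max(0, anchor_pos - w)
        hi = min(annot.length, anchor_pos + w)
        n_tx[(lo - anchor_pos) + w : (hi - anchor_pos) + w] += 1
        rows, cols = np.nonzero(grid.counts)
        for r, p in zip(rows, cols):
            n = int(grid.counts[r, p])
            length = grid.min_length + int(r)
            if use_asite:
                a = asite_position(int(p), length, table, annot.length)
                if a is None:
                    continue
                pos = a
            else:
                pos = int(p)
            i = pos - anchor_pos + w
            if 0 <= i < 2 * w:
                counts[i] += n
                if length_stratified:
                    strat.setdefault(
                        length, np.zeros(2 * w, dtype=np.int64)
                    )[i] += n
    return MetageneProfile(
        anchor, rel, counts, n_tx, strat if length_stratified else None
    )


def periodicity_score(
    profile: MetageneProfile | np.ndarray,
) -> tuple[float, float]:
    """Spectral three-nucleotide periodicity of a metagene profile.

    The mean-subtracted profile is Fourier-transformed; the score is the
    magnitude at period 3 divided by the total non-DC magnitude, in [0, 1].
    A flat profile has no non-DC energy and scores 0 by convention.  Returns
    ``(score, dominant_period)``.
    """
    x = profile.counts if isinstance(profile, MetageneProfile) else np.asarray(profile)
    n = len(x)
    if n < 6 or n % 3 != 0:
        raise SummaryError(
            f"profile length {n} must be >= 6 and a multiple of 3"
        )
    spectrum = np.abs(np.fft.rfft(x - x.mean()))
    mags = spectrum[1:]  # drop DC
    total = mags.sum()
    if total == 0:
        return 0.0, float("nan")
    k3 = n // 3  # the exact period-3 bin
    score = float(spectrum[k3] / total)
    k_dom = int(np.argmax(mags)) + 1
    return score, n / k_dom


# ---------------------------------------------------------------------------
# Gene-level quantification


def gene_counts_and_tpm(
    densities: Mapping[str, CodonDensity],
    annotation: AnnotationSet,
) -> pd.DataFrame:
    """Per-gene footprint counts, per-codon density and TPM.

    The gene-level count is the number of CDS-assigned A-site footprints
    (an ORF quantity, not all transcript-mapped reads).  TPM divides each
    gene's count rate (count per CDS codon) by the sample total and scales
    to 1e6, so the column sums to 1e6 for any sample with signal.  An
    all-zero sample is degenerate: TPM is set to 0 and the ``degenerate``
    column flags every row, rather than propagating NaN.
    """
    tids = list(densities)
    counts = np.array([densities[t].total for t in tids], dtype=np.int64)
    n_codons = np.array([annotation[t].n_codons for t in tids], dtype=np.int64)
    rate = counts / n_codons
    total_rate = rate.sum()
    degenerate = total_rate == 0
    tpm = np.zeros_like(rate) if degenerate else 1e6 * rate / total_rate
    if degenerate:
        log.warning("all-zero sample: TPM undefined, reported as 0 and flagged")
    return pd.DataFrame(
        {
            "transcript_id": tids,
            "count": counts,
            "cds_length_codons": n_codons,
            "density": rate,
            "tpm": tpm,
            "degenerate": degenerate,
        }
    )


def join_count_matrix(samples: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Genes x samples integer count matrix with explicit zeros.

    The output is directly usable as input to count-based differential
    expression tools (DESeq2-style: one row per gene, one column per
    sample).
    """
    cols = {}
    for name, quant in samples.items():
        cols[name] = quant.set_index("transcript_id")["count"]
    mat = pd.DataFrame(cols).fillna(0).astype(np.int64)
    mat.index.name = "transcript_id"
    return mat


# ---------------------------------------------------------------------------
# Codon-specific density vs an external per-codon feature


@dataclasses.dataclass
class CodonCorrelation:
    rho: float
    p_value: float
    n_genes: int
    table: pd.DataFrame
    degenerate: bool = False


def mean_normalized_codon_density(
    densities: Mapping[str, CodonDensity],
    annotation: AnnotationSet,
    min_reads: int = DEFAULT_MIN_READS,
    exclude_terminal_codons: int = 1,
) -> tuple[pd.Series, int]:
    """Mean normalized density per codon identity across genes.

    Each qualifying gene's codon vector is divided by its own mean over
    covered codons (depth normalization), then every (gene, position) pair
    contributes its normalized value to its codon identity.  The first and
    final ``exclude_terminal_codons`` codons are skipped: initiation and
    termination dwell there, not elongation.  Returns (per-codon means over
    the 61 sense codons, number of qualifying genes).
    """
    sums: Counter = Counter()
    ns: Counter = Counter()
    n_genes = 0
    for tid, d in densities.items():
        if d.total < min_reads:
            continue
        annot = annotation[tid]
        vec = d.counts.astype(float)
        covered = vec > 0
        if not covered.any():
            continue
        norm = vec / vec[covered].mean()
        n_genes += 1
        lo = exclude_terminal_codons
        hi = annot.n_codons - 1 - exclude_terminal_codons  # also drops stop
        for c in range(lo, hi):
            codon = annot.codon(c)
            if codon in STOP_CODONS or "N" in codon:
                continue
            sums[codon] += norm[c]
            ns[codon] += 1
    means = pd.Series(
        {c: (sums[c] / ns[c] if ns[c] else np.nan) for c in SENSE_CODONS},
        name="mean_normalized_density",
    )
    means.index.name = "codon"
    return means, n_genes


def codon_feature_correlation(
    densities: Mapping[str, CodonDensity],
    annotation: AnnotationSet,
    feature: Mapping[str, float],
    min_reads: int = DEFAULT_MIN_READS,
    n_permutations: int = 1999,
    seed: int = 0,
) -> CodonCorrelation:
    """Spearman correlation of codon-specific density with a codon feature.

    ``feature`` must cover all 61 sense codons (e.g. tRNA gene copy
    numbers).  Significance is assessed by permuting the feature values over
    codon identities (assumption-free, handles ties), with the observed
    statistic included in the null per the standard permutation estimator.
    """
    missing = [c for c in SENSE_CODONS if c not in feature]
    if missing:
        raise SummaryError(
            f"feature table missing {len(missing)} sense codons "
            f"(e.g. {missing[:5]})"
        )
    means, n_genes = mean_normalized_codon_density(
        densities, annotation, min_reads
    )
    if n_genes == 0:
        raise SummaryError(f"no gene passes min_reads={min_reads}")
    feat = pd.Series({c: float(feature[c]) for c in SENSE_CODONS}, name="feature")
    table = pd.concat([means, feat], axis=1).reset_index(names="codon")
    ok = table["mean_normalized_density"].notna()
    x = table.loc[ok, "mean_normalized_density"].to_numpy()
    y = table.loc[ok, "feature"].to_numpy()
    if len(np.unique(y)) < 2 or len(np.unique(x)) < 2 or len(x) < 3:
        return CodonCorrelation(0.0, 1.0, n_genes, table, degenerate=True)
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        r = float(stats.spearmanr(x, rng.permutation(y)).statistic)
        if abs(r) >= abs(rho):
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return CodonCorrelation(rho, p, n_genes, table)


# ---------------------------------------------------------------------------
# Convenience: everything for one sample


def codon_densities_for_sample(
    grids: Mapping[str, Ribogrid],
    annotation: AnnotationSet,
    table: AsiteOffsetTable,
) -> tuple[dict[str, CodonDensity], dict[str, Counter]]:
    densities: dict[str, CodonDensity] = {}
    exclusions: dict[str, Counter] = {}
    for tid, grid in grids.items():
        d, exc = codon_density_from_grid(grid, annotation[tid], table)
        densities[tid] = d
        exclusions[tid] = exc
    return densities, exclusions
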