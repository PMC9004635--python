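# Methods

## Scope and data model

The package analyses ribosome footprints that are already aligned to a
*transcriptome*: every reference sequence is one spliced transcript (or one
ORF with fixed-width pads), so all coordinates are transcript-local, all
features sit on the plus strand, and there is no exon arithmetic. Reads
antisense to a transcript are not footprints of ribosomes on that
transcript and are discarded rather than reverse-complemented.

All internal coordinates are 0-based half-open. The 1-based inclusive
convention appears only at the GFF3 boundary (converted as
`[start−1, end)`) and in text reports. A CDS runs from the first base of
the start codon through the last base of the stop codon; its length must be
a multiple of 3, and transcripts violating this are excluded with a warning
by default (frame statistics are undefined for them) or rejected outright
in strict mode. Multiple CDS lines on one transcript are merged only when
contiguous; a gapped CDS indicates a genome-style annotation, which is out
of scope.

## The ribogrid and its H5 schema

For each transcript the ribogrid stores the integer matrix
`C[ℓ − ℓ_min, p]`: footprints of aligned length ℓ (soft clips excluded)
with 5ʹ end at position p. Length bounds default to 10–50 nt, spanning
reported footprint sizes across bacteria, archaea and eukaryotes;
transcripts without footprints keep explicit zero grids so gene-level count
matrices are complete (count-based differential-expression tools need all
genes). A footprint may not overhang the 3ʹ end; the builder enforces this.

The HDF5 layout is self-describing:

- root attributes: `schema_version` (`"1.0"`), `sample_name`, `min_length`,
  `max_length`, optional `tool_version`, `source_bam`, `created`;
- one group per transcript (creation order preserved via HDF5 order
  tracking), with attributes `transcript_length`, `cds_start`, `cds_end`
  (0-based half-open) and a 2-D integer dataset `reads` (rows = lengths
  ascending, columns = positions), chunked and gzip-compressed.

Compression is lossless and the reader validates every required attribute,
so write→read is bit-exact and schema violations fail loudly with the
offending name. The `created` timestamp is written only when the caller
supplies one: by default two identical runs produce byte-identical files,
which the test suite asserts. The matrix is always indexed by the 5ʹ end,
even when A-site assignment anchors at the 3ʹ end (derived as
`p + ℓ − 1` at query time); storing a single convention avoids duplicated
state.

## A-site assignment

The displacement table maps read length → displacement, anchored at the 5ʹ
or 3ʹ read end (`a = p + d[ℓ]` or `a = p + ℓ − 1 − d[ℓ]`). The two
anchorings are exact duals under `d ↔ ℓ − 1 − d`; this identity is used as
a cross-check in the tests. **Convention:** the assigned position `a` is
the *first nucleotide of the A-site codon*. Displacement tables in the
wild differ in whether they point at the A or P site and at which base; any
such table can be expressed here, but comparisons across tools must align
on this convention. The shipped default `{26:14, 27:14, 28:15, 29:15,
30:15, 31:16, 32:16}` (5ʹ-anchored) is the standard yeast-style choice and
is fully user-overridable; automatic offset calibration from data is
intentionally not provided — the displacement is an explicit, user-owned
parameter.

Reads whose length is absent from the table, whose computed `a` leaves the
transcript, or whose `a` falls outside the CDS are excluded from codon
density and tallied by reason; conservation
(`density + exclusions = grid total`) holds per transcript and is asserted
end-to-end.

## Reading frames, metagene, periodicity

Frame is `(a − cds_start) mod 3` with the mathematical modulus, so
positions upstream of the start codon still land in {0, 1, 2}. By default
frame statistics use the A-site-corrected position; a `frame_from="pos5"`
switch computes them from the raw 5ʹ end instead — the view in which
untrimmed non-templated 5ʹ additions visibly corrupt frame statistics. Per
gene, proportions are exact rationals of counts; genes below `min_reads`
(default 64) are flagged low-coverage because proportions from a handful of
reads are noise.

The metagene profile pools footprint 5ʹ-end counts (optionally A-site
counts) at positions relative to the start (or stop) codon's first
nucleotide, over the half-open window `[−3w, +3w)` with `w` = 25 codons by
default. The half-open window makes the profile length `6w` a multiple
of 3, so the discrete Fourier spectrum has an exact period-3 bin. The
per-position count of covering transcripts is returned for normalization;
transcripts with short pads contribute only covered positions.

The periodicity score is the magnitude of the mean-subtracted profile's
DFT at period 3 divided by the total non-DC magnitude (range [0, 1]; a
flat profile scores 0 by convention). Diagnostics score the *in-CDS
segment* (relative positions ≥ 0): the coverage step at the start codon
otherwise leaks into all low-frequency bins and can dominate the period-3
line even in strongly periodic data.

## Gene quantification

Gene count = CDS-assigned A-site footprints (an ORF quantity, not all
transcript-mapped reads — relevant when comparing with pipelines that
count whole-transcript coverage). With `L_g` the CDS length in codons,
`TPM_g = 10⁶ · (count_g/L_g) / Σ_h (count_h/L_h)`; the column sums to 10⁶
within floating-point rounding. An all-zero sample is flagged degenerate
with TPM 0 rather than propagating NaN. Multi-sample counts join into a
genes × samples integer matrix with explicit zeros.

## Codon density vs per-codon features

To compare codon-specific density with an external feature (e.g. tRNA gene
copy numbers), each qualifying gene's codon vector is divided by its own
mean over covered codons — removing gene-level depth so deep genes do not
dominate — and every (gene, position) pair contributes its normalized
value to its codon identity. The first and last sense codon of each CDS
are skipped (initiation/termination dwell, not elongation) and stop codons
never enter the 61-codon table. Association is summarized by Spearman rank
correlation with a permutation p-value (feature values permuted over codon
identities, observed statistic included in the null): 61 tied, non-normal
observations are exactly the situation where the asymptotic formula is
least trustworthy.

## Pre- and post-alignment library handling

**Demultiplexing.** A read is assigned to the unique sample whose barcode
is within `max_mismatches` (default 1) Hamming distance of the observed
barcode region; equidistant qualifying ties are conservatively routed to
`Unassigned` (mis-assignment is worse than loss). A sheet whose barcodes
are closer than `2·max_mismatches` is rejected outright, since a single
error could then flip an assignment; at exactly `2·max_mismatches` only
exact ties are possible and those are already handled. Read conservation
(Σ per-sample + Unassigned = input) is asserted.

**UMI handling.** UMI bases are moved from the sequence (and quality, in
lockstep) into an underscore-delimited identifier suffix — the convention
downstream deduplication tools consume — so users can still run external
network-based deduplication. The in-scope deduplicator is exact-match
only: among alignments sharing (transcript, 5ʹ position, length, UMI) the
first in sort order survives. Directional-adjacency collapsing is
deliberately out of scope.

**5ʹ-mismatch trimming.** Some (notably viral) reverse transcriptases add
non-templated bases to cDNA 5ʹ ends; after alignment these appear as a
mismatch run anchored at read offset 0 and shift the apparent 5ʹ position,
corrupting frame statistics. The trimmer removes exactly the terminal run
`k` (computed from the MD tag; no reference FASTA needed), rewriting POS,
CIGAR, MD and NM consistently; `k > max_trim` (default 2) sends the record
to a discard stream, since longer terminal mismatch runs more likely
indicate mis-mapping. Isolated internal mismatches never trigger trimming,
the operation is idempotent, and records with gapped or clipped 5ʹ termini
pass through untouched under a warning counter. The paired simulation
(below) demonstrates the frame-restoring effect.

## The simulator (test oracle)

The generator emulates a padded-ORFeome experiment with everything planted
and recorded:

- transcriptome: `pad + ATG + random sense codons + stop + pad`; defaults
  100 transcripts, 100–300 codons, 50 nt pads (wide enough to absorb any
  planted displacement, checked at spec validation);
- molecules: gene ∼ lognormal abundances (σ = 0.75); A-site codon within
  the gene ∼ per-codon dwell of the codon identity (uniform when none is
  planted; the stop codon is never an A-site); frame ∼ `frame_weights`
  (default 0.85/0.10/0.05); length ∼ `length_weights` (default centred on
  28-mers); 5ʹ position derived by inverting the planted displacement;
- artefacts: non-templated 5ʹ additions (1–2 bases, each sampled to
  mismatch the reference, applied per molecule *before* PCR so duplicates
  remain exact copies), PCR duplication (1 + Poisson), per-molecule UMIs,
  per-read sample barcodes with a 0/1/2-mutation mixture.

The BAM is written directly as if perfectly aligned, with internally
consistent CIGAR/MD/NM — alignment software is out of scope and tests must
not depend on it. All randomness flows from one seed through independent
named child streams, so (a) outputs are byte-reproducible and (b) an
artefact can be toggled without changing the underlying molecules: the
trim-efficacy analysis compares a `p_addition = 0.3` library against its
`p = 0` twin as a paired design.

What the simulator does *not* model: sequencing errors inside the fragment,
quality-score structure, rRNA contamination, biased fragment ends, or
multi-mapping. Passing tests therefore demonstrate the correctness of the
accounting and the statistics on clean alignments, not robustness to
alignment artefacts in real libraries.

## Orchestration and reproducibility

A single YAML file configures a run; unknown keys are rejected by name and
validation returns the complete error list before any stage executes. Per
sample the stages are: optional 5ʹ trim → optional dedup → filter →
ribogrid H5 → summaries → plots → HTML report; a failing sample is
recorded in the run manifest (with input SHA-256 hashes, parameters and
tool version) without aborting the others. With a fixed seed and no
timestamp configured, reruns are byte-identical for H5 and TSV outputs;
the manifest records everything needed to re-execute a run. Plots never
compute statistics and each image has a sibling TSV of exactly what was
drawn, so tests assert on data, never pixels.

## Problem sizes and numerical choices

The verification suite uses desk-scale simulations: count conservation at
2,000 transcripts / 100,000 footprints; statistical recovery at ~2,000
reads per gene (binomial/multinomial 3-standard-error bands); the dwell
correlation at 10⁵ reads over 50 genes against a 61-codon feature table;
paired trim comparisons over 10 seeds; periodicity over 20 replicate
pairs. Exact properties (conservation, roundtrip, duality,
grid-vs-stream equivalence, determinism) are asserted with zero
tolerance; statistical properties use the stated sampling bounds. TPM
sums are checked to 10⁻⁶ relative.

## Known limitations

- One CDS per transcript; extra ORFs on a sequence are reported, not
  analysed.
- Ungapped footprint alignments only; indel-containing or 5ʹ-clipped
  records pass through the trimmer untrimmed and are counted.
- Exact-match deduplication will under-collapse UMIs with sequencing
  errors (by design; use a network-based tool for that).
- The interactive exploration layer is replaced by static plots plus
  machine-readable exports; any front-end can be built on those.
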