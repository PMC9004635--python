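"""Demultiplexing, UMI extraction and exact deduplication."""

import itertools

import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribogridkit.preprocess import (
    UNASSIGNED,
    BarcodeSheet,
    FastqRead,
    PreprocessError,
    UmiSpec,
    assign_barcode,
    dedup_exact,
    demultiplex,
    extract_umi,
    extract_umi_read,
    hamming,
    load_barcode_sheet,
    read_fastq,
    write_fastq,
)
from ribogridkit.simulate import SimulationSpec, simulate_footprints, simulate_transcriptome

from conftest import bam_header, make_bam_record


def fq(seq: str, name: str = "r1") -> FastqRead:
    return FastqRead(name, seq, "I" * len(seq))


class TestBarcodeSheet:
    def test_close_barcodes_rejected(self):
        # distance 1 < 2*1: a single error can flip the assignment
        with pytest.raises(PreprocessError, match="mismatches apart"):
            BarcodeSheet((("S1", "ACGT"), ("S2", "ACGA")), max_mismatches=1)

    def test_duplicate_names_and_barcodes_rejected(self):
        with pytest.raises(PreprocessError):
            BarcodeSheet((("S1", "ACGT"), ("S1", "TTTT")), 0)
        with pytest.raises(PreprocessError):
            BarcodeSheet((("S1", "ACGT"), ("S2", "ACGT")), 0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(PreprocessError, match="equal length"):
            BarcodeSheet((("S1", "ACGT"), ("S2", "TTTTT")), 0)

    def test_sheet_tsv_roundtrip(self, tmp_path):
        (tmp_path / "sheet.tsv").write_text("S1\tACGT\nS2\tTTTT\n")
        sheet = load_barcode_sheet(tmp_path / "sheet.tsv", max_mismatches=1)
        assert sheet.samples == ["S1", "S2"]
        assert sheet.barcode_length == 4


class TestAssignBarcode:
    @pytest.fixture
    def sheet(self):
        return BarcodeSheet((("S1", "ACGT"), ("S2", "TTTT")), max_mismatches=1)

    def test_within_budget_assigned(self, sheet):
        assert assign_barcode("ACGAGGGG", sheet) == "S1"

    def test_beyond_budget_unassigned(self, sheet):
        # GGGG: distance 3 to ACGT, 2 to TTTT -> both exceed budget 1
        assert assign_barcode("GGGGAAAA", sheet) is None

    def test_equidistant_tie_is_unassigned(self):
        sheet = BarcodeSheet((("S1", "AAAA"), ("S2", "TTTT")), max_mismatches=2)
        # AATT is distance 2 from both: qualifying tie -> conservative drop
        assert assign_barcode("AATTCCCC", sheet) is None

    def test_barcode_longer_than_read_errors(self, sheet):
        with pytest.raises(PreprocessError, match="shorter than barcode"):
            assign_barcode("ACG", sheet)


class TestDemultiplex:
    @pytest.fixture
    def sheet(self):
        return BarcodeSheet(
            (("S1", "ACACACAC"), ("S2", "AGAGAGAG"), ("S3", "ATATATAT")),
            max_mismatches=1,
        )

    def test_conservation_and_files(self, sheet, tmp_path):
        reads = [
            fq("ACACACAC" + "G" * 20, "a"),
            fq("ACACACAA" + "G" * 20, "b"),   # 1 mismatch -> S1
            fq("AGAGAGAG" + "G" * 20, "c"),
            fq("CCCCCCCC" + "G" * 20, "d"),   # nowhere close
        ]
        counts = demultiplex(reads, sheet, outdir=tmp_path)
        assert counts["S1"] == 2 and counts["S2"] == 1
        assert counts[UNASSIGNED] == 1
        assert sum(counts.values()) == len(reads)
        s1 = list(read_fastq(tmp_path / "S1.fastq"))
        assert [r.name for r in s1] == ["a", "b"]
        assert (tmp_path / "demultiplex_counts.tsv").exists()

    def test_zero_mismatch_equals_exact_prefix_match(self):
        """Oracle: naive prefix comparison, exhaustive over 4-mers."""
        sheet = BarcodeSheet(
            (("S1", "ACGT"), ("S2", "TGCA")), max_mismatches=0
        )
        lookup = {"ACGT": "S1", "TGCA": "S2"}
        for prefix in map("".join, itertools.product("ACGT", repeat=4)):
            expected = lookup.get(prefix)
            assert assign_barcode(prefix + "GGGG", sheet) == expected


class TestExtractUmi:
    def test_five_prime_umi(self):
        out = extract_umi_read(fq("AAAACCCGGG"), UmiSpec(umi5_length=4))
        assert out.sequence == "CCCGGG"
        assert out.name == "r1_AAAA"
        assert len(out.quality) == 6

    def test_identity_when_no_umi(self):
        read = fq("AAAACCCGGG")
        assert extract_umi_read(read, UmiSpec()) == read

    def test_both_end_umis(self):
        out = extract_umi_read(fq("TTACGTACGAA"), UmiSpec(2, 3))
        assert out.sequence == "ACGTAC"
        assert out.name.endswith("_TTGAA")

    def test_in_read_barcode_removed(self):
        out = extract_umi_read(
            fq("CCCCAAGGGTTT"), UmiSpec(2, 0, barcode_in_read=(0, 4))
        )
        assert out.sequence == "GGGTTT"
        assert out.name == "r1_AA"

    def test_too_short_rejected_not_dropped(self):
        accepted, rejected = extract_umi([fq("ACGT")], UmiSpec(3, 2))
        assert accepted == [] and len(rejected) == 1

    @given(
        umi5=st.integers(0, 4),
        umi3=st.integers(0, 4),
        core=st.text(alphabet="ACGT", min_size=10, max_size=30),
        umis=st.text(alphabet="ACGT", min_size=8, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_reattachment_reconstructs_original(self, umi5, umi3, core, umis):
        """extract_umi is invertible given the recorded UMI."""
        seq = umis[:umi5] + core + umis[4 : 4 + umi3]
        out = extract_umi_read(fq(seq), UmiSpec(umi5, umi3))
        if umi5 or umi3:
            umi = out.name.rsplit("_", 1)[1]
            rebuilt = umi[:umi5] + out.sequence + umi[umi5:]
        else:
            rebuilt = out.sequence
        assert rebuilt == seq

    def test_fastq_file_roundtrip(self, tmp_path):
        reads = [fq("ACGTACGT", "x"), fq("TTTTCCCC", "y")]
        write_fastq(reads, tmp_path / "r.fastq")
        assert list(read_fastq(tmp_path / "r.fastq")) == reads


class TestDedupExact:
    def _write(self, path, records, header):
        with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
            for rec in records:
                bam.write(rec)

    def test_exact_duplicates_collapse(self, t1_annotation, tmp_path):
        header = bam_header(t1_annotation)
        recs = [
            make_bam_record(header, "a_AAAA", 0, 10, "A" * 28),
            make_bam_record(header, "b_AAAA", 0, 10, "A" * 28),  # dup
            make_bam_record(header, "c_AAAT", 0, 10, "A" * 28),  # distinct UMI
        ]
        self._write(tmp_path / "in.bam", recs, header)
        kept, removed = dedup_exact(tmp_path / "in.bam", tmp_path / "out.bam")
        assert (kept, removed) == (2, 1)

    def test_missing_umi_suffix_errors(self, t1_annotation, tmp_path):
        header = bam_header(t1_annotation)
        self._write(
            tmp_path / "in.bam",
            [make_bam_record(header, "noumisuffix", 0, 10, "A" * 28)],
            header,
        )
        with pytest.raises(PreprocessError, match="noumisuffix"):
            dedup_exact(tmp_path / "in.bam", tmp_path / "out.bam")

    def test_simulated_duplicates_reduce_to_molecules(self, tmp_path):
        """The simulator knows the true molecule count; dedup recovers it."""
        spec = SimulationSpec(
            n_transcripts=5, depth=200, seed=5,
            pcr_duplication=3.0, umi_length=10,
        )
        ann = simulate_transcriptome(spec)
        res = simulate_footprints(spec, ann, tmp_path)
        assert len(res.manifest) > spec.depth  # duplication actually happened
        kept, removed = dedup_exact(res.bam_path, tmp_path / "dedup.bam")
        assert kept == res.manifest["molecule"].nunique() == spec.depth
        assert kept + removed == len(res.manifest)
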