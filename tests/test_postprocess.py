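"""5'-mismatch trimming and alignment filtering."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribogridkit.postprocess import (
    AlignedFootprint,
    FilterReport,
    PostprocessError,
    encode_md,
    expand_md,
    filter_alignments,
    trim_5p_mismatch,
    trim_bam,
)
from ribogridkit.simulate import SimulationSpec, simulate_footprints, simulate_transcriptome

from conftest import bam_header, make_bam_record


def naive_mismatches(read: str, reference: str, pos: int) -> list[int]:
    """Independent oracle: compare read to reference base by base."""
    return [
        i for i, base in enumerate(read) if base != reference[pos + i]
    ]


class TestMdCodec:
    @pytest.mark.parametrize(
        "md, expanded",
        [
            ("28", [None] * 28),
            ("0C27", ["C"] + [None] * 27),
            ("0C0A26", ["C", "A"] + [None] * 26),
            ("10A17", [None] * 10 + ["A"] + [None] * 17),
        ],
    )
    def test_examples(self, md, expanded):
        assert expand_md(md) == expanded
        assert encode_md(expanded) == md

    @given(
        st.lists(
            st.one_of(st.none(), st.sampled_from("ACGT")),
            min_size=1, max_size=60,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_roundtrip(self, entries):
        assert expand_md(encode_md(entries)) == entries

    def test_deletion_unsupported(self):
        with pytest.raises(PostprocessError, match="deletion"):
            expand_md("10^AC18")


class TestTrim5pMismatch:
    def _record(self, header, ref_seq, pos, read_seq, name="r_AAAA"):
        """Build a record whose MD/NM are derived by the naive oracle."""
        mism = naive_mismatches(read_seq, ref_seq, pos)
        entries = [
            ref_seq[pos + i] if i in mism else None
            for i in range(len(read_seq))
        ]
        return make_bam_record(
            header, name, 0, pos, read_seq,
            md=encode_md(entries), nm=len(mism),
        )

    @pytest.fixture
    def setup(self, t1_annotation):
        ref = t1_annotation["T1"].sequence
        return bam_header(t1_annotation), ref

    def test_all_match_unchanged(self, setup):
        header, ref = setup
        rec = self._record(header, ref, 5, ref[5:33])
        status, k = trim_5p_mismatch(rec, max_trim=2)
        assert (status, k) == ("trimmed", 0)
        assert rec.reference_start == 5
        assert rec.query_alignment_length == 28

    def test_single_terminal_mismatch_trimmed(self, setup):
        """28 nt read, base 0 mismatching: 27 nt survive, POS+1, NM-1."""
        header, ref = setup
        read = ("A" if ref[5] != "A" else "C") + ref[6:33]
        rec = self._record(header, ref, 5, read)
        status, k = trim_5p_mismatch(rec, max_trim=2)
        assert (status, k) == ("trimmed", 1)
        assert rec.reference_start == 6
        assert rec.query_sequence == ref[6:33]
        assert rec.get_tag("NM") == 0
        # re-derive mismatches from the rewritten record: none at offset 0
        assert naive_mismatches(rec.query_sequence, ref, 6) == []
        assert expand_md(rec.get_tag("MD")) == [None] * 27

    def test_run_exceeding_budget_rejected(self, setup):
        header, ref = setup
        bad = "".join("A" if ref[5 + i] != "A" else "C" for i in range(3))
        rec = self._record(header, ref, 5, bad + ref[8:33])
        status, k = trim_5p_mismatch(rec, max_trim=2)
        assert (status, k) == ("rejected", 3)

    def test_internal_mismatch_never_triggers_trimming(self, setup):
        header, ref = setup
        read = list(ref[5:33])
        read[10] = "A" if read[10] != "A" else "C"
        rec = self._record(header, ref, 5, "".join(read))
        status, k = trim_5p_mismatch(rec, max_trim=2)
        assert (status, k) == ("trimmed", 0)
        assert rec.get_tag("NM") == 1  # untouched

    def test_record_without_md_errors(self, setup):
        header, ref = setup
        rec = make_bam_record(header, "r", 0, 5, ref[5:33])
        with pytest.raises(PostprocessError, match="MD"):
            trim_5p_mismatch(rec)

    def test_idempotent_on_simulated_library(self, sim_messy, tmp_path):
        """Trimming twice equals trimming once, record for record."""
        _spec, _ann, res, _ = sim_messy
        once = tmp_path / "once.bam"
        twice = tmp_path / "twice.bam"
        s1 = trim_bam(res.bam_path, once, max_trim=2)
        s2 = trim_bam(once, twice, max_trim=2)
        assert s2.n_rejected == 0
        assert sum(k * v for k, v in s2.n_trimmed.items()) == 0
        with pysam.AlignmentFile(str(once), check_sq=False) as a, \
             pysam.AlignmentFile(str(twice), check_sq=False) as b:
            for ra, rb in zip(a.fetch(until_eof=True), b.fetch(until_eof=True)):
                assert ra.to_string() == rb.to_string()
        assert s1.n_total == len(res.manifest)

    def test_trim_restores_simulated_fragments(self, sim_messy, tmp_path):
        """After trimming, positions/lengths equal the templated truth."""
        _spec, ann, res, _ = sim_messy
        out = tmp_path / "trimmed.bam"
        summary = trim_bam(res.bam_path, out, max_trim=2)
        n_added = res.manifest.groupby("n_added_5p").size().to_dict()
        assert dict(summary.n_trimmed) == {
            k: v for k, v in n_added.items()
        }
        truth = {
            (r.read_id, r.transcript): (r.pos5, r.length)
            for r in res.manifest.itertuples()
        }
        with pysam.AlignmentFile(str(out), check_sq=False) as bam:
            for rec in bam.fetch(until_eof=True):
                pos5, length = truth[(rec.query_name, rec.reference_name)]
                assert rec.reference_start == pos5
                assert rec.query_alignment_length == length


class TestFilterAlignments:
    def test_empty_bam(self, t1_annotation, tmp_path):
        header = bam_header(t1_annotation)
        with pysam.AlignmentFile(str(tmp_path / "e.bam"), "wb", header=header):
            pass
        fps, report = filter_alignments(tmp_path / "e.bam", t1_annotation)
        assert fps == [] and report.n_total == 0

    def test_rejection_reasons(self, t1_annotation, tmp_path):
        header = bam_header(t1_annotation)
        recs = [
            make_bam_record(header, "unmapped", 0, 10, "A" * 28, flag=4),
            make_bam_record(header, "secondary", 0, 10, "A" * 28, flag=256),
            make_bam_record(header, "short", 0, 10, "A" * 9),
            make_bam_record(header, "ok1", 0, 10, "A" * 28),
            make_bam_record(header, "ok2", 0, 12, "A" * 30),
        ]
        path = tmp_path / "f.bam"
        with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
            for rec in recs:
                bam.write(rec)
        fps, report = filter_alignments(path, t1_annotation, 10, 50)
        assert report.n_accepted == 2
        assert dict(report.reasons) == {
            "unmapped": 1, "secondary": 1, "too_short": 1
        }
        assert report.n_total == 5
        assert fps[0] == AlignedFootprint("T1", 10, 28)
        assert fps[0].pos3 == 37

    def test_unknown_reference_errors(self, t1_annotation, tmp_path):
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "ghost", "LN": 100}]}
        )
        path = tmp_path / "g.bam"
        with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
            bam.write(make_bam_record(header, "r", 0, 0, "A" * 28))
        with pytest.raises(PostprocessError, match="ghost"):
            filter_alignments(path, t1_annotation)

    def test_simulator_composition_matches_report(self, sim_small):
        """The simulation manifest is the oracle for the filter report."""
        spec, ann, res, _ = sim_small
        fps, report = filter_alignments(res.bam_path, ann, 10, 50)
        assert report.n_accepted == len(res.manifest)
        assert sum(report.reasons.values()) == 0
        lengths = np.array([fp.read_length for fp in fps])
        assert sorted(np.unique(lengths)) == sorted(spec.length_weights)
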