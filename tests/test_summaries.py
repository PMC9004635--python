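"""Length distribution, frame proportions, metagene/periodicity, TPM,
codon-feature correlation."""

import numpy as np
import pandas as pd
import pytest

from ribogridkit.annotation import AnnotationSet, TranscriptAnnotation
from ribogridkit.asite import AsiteOffsetTable, CodonDensity
from ribogridkit.grid import Ribogrid, build_ribogrid
from ribogridkit.postprocess import AlignedFootprint, filter_alignments
from ribogridkit.summaries import (
    SENSE_CODONS,
    SummaryError,
    codon_densities_for_sample,
    codon_feature_correlation,
    frame_proportions_per_gene,
    gene_counts_and_tpm,
    join_count_matrix,
    length_distribution,
    metagene_profile,
    periodicity_score,
    pooled_frame_proportions,
)

TABLE28 = AsiteOffsetTable("five_prime", {28: 15})


def single_gene_annotation(n_codons=20, pad=30, tid="T1"):
    seq = "C" * pad + "ATG" + "GCT" * (n_codons - 2) + "TAA" + "C" * pad
    ann = AnnotationSet()
    ann.add(TranscriptAnnotation(tid, seq, pad, pad + 3 * n_codons))
    return ann


class TestLengthDistribution:
    def test_single_grid(self, t1_annotation):
        fps = [AlignedFootprint("T1", 10, 28)] * 2 + [AlignedFootprint("T1", 11, 30)]
        grids = build_ribogrid(fps, t1_annotation, 25, 35)
        dist = length_distribution(grids)
        assert dist[28] == 2 and dist[30] == 1 and dist.sum() == 3

    def test_additivity_across_grids(self, sim_small):
        _spec, ann, res, _ = sim_small
        fps, _ = filter_alignments(res.bam_path, ann, 10, 50)
        grids = build_ribogrid(fps, ann, 10, 50)
        ids = list(grids)
        half_a = {t: grids[t] for t in ids[: len(ids) // 2]}
        half_b = {t: grids[t] for t in ids[len(ids) // 2 :]}
        total = length_distribution(grids)
        summed = length_distribution(half_a).add(
            length_distribution(half_b), fill_value=0
        )
        pd.testing.assert_series_equal(total, summed.astype(np.int64))

    def test_mixed_bounds_rejected(self, t1_annotation):
        grids = {
            "A": Ribogrid.zeros("A", 60, 25, 35),
            "B": Ribogrid.zeros("B", 60, 20, 35),
        }
        with pytest.raises(SummaryError, match="mixed"):
            length_distribution(grids)

    def test_simulated_proportions_within_three_se(self, sim_small):
        spec, ann, res, _ = sim_small
        fps, _ = filter_alignments(res.bam_path, ann, 10, 50)
        dist = length_distribution(build_ribogrid(fps, ann, 10, 50))
        n = dist.sum()
        for length, p in spec.length_weights.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(dist[length] / n - p) < 3 * se + 1e-12, length


class TestFrameProportions:
    def test_pure_frame0(self):
        ann = single_gene_annotation()
        t = ann["T1"]
        fps = [AlignedFootprint("T1", t.cds_start + 3 * c - 15, 28)
               for c in range(2, 10)]
        grids = build_ribogrid(fps, ann, 25, 35)
        table = frame_proportions_per_gene(grids, ann, TABLE28, min_reads=1)
        row = table.iloc[0]
        assert (row.p0, row.p1, row.p2) == (1.0, 0.0, 0.0)

    def test_exact_rational_proportions(self):
        """Counts (6, 3, 3) across frames -> proportions (0.5, 0.25, 0.25)."""
        ann = single_gene_annotation()
        t = ann["T1"]
        base = t.cds_start + 9 - 15
        fps = (
            [AlignedFootprint("T1", base, 28)] * 6
            + [AlignedFootprint("T1", base + 1, 28)] * 3
            + [AlignedFootprint("T1", base + 2, 28)] * 3
        )
        grids = build_ribogrid(fps, ann, 25, 35)
        row = frame_proportions_per_gene(grids, ann, TABLE28, min_reads=1).iloc[0]
        assert (row.n_frame0, row.n_frame1, row.n_frame2) == (6, 3, 3)
        assert (row.p0, row.p1, row.p2) == (0.5, 0.25, 0.25)
        assert not row.low_coverage

    def test_zero_count_gene_flagged_with_nan_proportions(self):
        ann = single_gene_annotation()
        grids = build_ribogrid([], ann, 25, 35)
        row = frame_proportions_per_gene(grids, ann, TABLE28).iloc[0]
        assert row.low_coverage and np.isnan(row.p0)

    def test_recovers_planted_weights_within_three_se(self, sim_small):
        spec, ann, res, _ = sim_small
        fps, _ = filter_alignments(res.bam_path, ann, 10, 50)
        grids = build_ribogrid(fps, ann, 10, 50)
        table = frame_proportions_per_gene(grids, ann, spec.offsets)
        pooled = pooled_frame_proportions(table)
        n = table["n_total"].sum()
        for i, p in enumerate(spec.frame_weights):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(pooled[i] - p) < 3 * se + 1e-12, i


class TestMetagene:
    def test_single_footprint_at_start(self):
        ann = single_gene_annotation(pad=80)
        t = ann["T1"]
        grids = build_ribogrid(
            [AlignedFootprint("T1", t.cds_start, 28)], ann, 25, 35
        )
        profile = metagene_profile(grids, ann, "start_codon", window_codons=25)
        assert profile.counts.sum() == 1
        assert profile.counts[np.where(profile.rel_positions == 0)[0][0]] == 1

    def test_no_footprints_gives_zero_profile(self):
        ann = single_gene_annotation()
        grids = build_ribogrid([], ann, 25, 35)
        profile = metagene_profile(grids, ann)
        assert profile.counts.sum() == 0
        assert len(profile.counts) == 150

    def test_short_pad_contributes_covered_positions_only(self):
        ann = single_gene_annotation(pad=30)  # pad < 75 nt window
        grids = build_ribogrid([], ann, 25, 35)
        profile = metagene_profile(grids, ann, window_codons=25)
        covered = profile.n_transcripts > 0
        assert profile.rel_positions[covered].min() == -30

    def test_additivity(self, sim_small):
        """profile(A union B) == profile(A) + profile(B)."""
        _spec, ann, res, _ = sim_small
        fps, _ = filter_alignments(res.bam_path, ann, 10, 50)
        grids = build_ribogrid(fps, ann, 10, 50)
        ids = list(grids)
        a = {t: grids[t] for t in ids[:10]}
        b = {t: grids[t] for t in ids[10:]}
        pa = metagene_profile(a, ann)
        pb = metagene_profile(b, ann)
        pall = metagene_profile(grids, ann)
        np.testing.assert_array_equal(pall.counts, pa.counts + pb.counts)

    def test_stop_codon_anchor(self):
        ann = single_gene_annotation(pad=80)
        t = ann["T1"]
        grids = build_ribogrid(
            [AlignedFootprint("T1", t.cds_end - 3, 28)], ann, 25, 35
        )
        profile = metagene_profile(grids, ann, anchor="stop_codon")
        assert profile.counts[np.where(profile.rel_positions == 0)[0][0]] == 1


class TestPeriodicityScore:
    def test_pure_impulse_train(self):
        x = np.zeros(60)
        x[::3] = 10
        score, period = periodicity_score(x)
        assert period == 3
        assert score > 0.95

    def test_constant_profile_scores_zero(self):
        score, period = periodicity_score(np.full(30, 7.0))
        assert score == 0.0 and np.isnan(period)

    @pytest.mark.parametrize("n", [5, 7, 100])
    def test_bad_length_rejected(self, n):
        with pytest.raises(SummaryError):
            periodicity_score(np.ones(n))

    def test_dft_oracle_on_periodic_simulation(self, sim_small):
        """Brute-force DFT: period-3 line dominates the in-CDS spectrum."""
        spec, ann, res, _ = sim_small
        fps, _ = filter_alignments(res.bam_path, ann, 10, 50)
        grids = build_ribogrid(fps, ann, 10, 50)
        profile = metagene_profile(grids, ann, window_codons=25)
        x = profile.downstream_counts().astype(float)
        x -= x.mean()
        n = len(x)
        # naive DFT, no FFT
        mags = [
            abs(sum(x[t] * np.exp(-2j * np.pi * k * t / n) for t in range(n)))
            for k in range(1, n // 2 + 1)
        ]
        assert np.argmax(mags) + 1 == n // 3
        score, period = periodicity_score(x)
        assert period == 3.0
        assert abs(score - mags[n // 3 - 1] / sum(mags)) < 1e-9


class TestGeneQuant:
    def _quant(self, counts_and_codons):
        ann = AnnotationSet()
        densities = {}
        for tid, (count, n_codons) in counts_and_codons.items():
            pad = 30
            seq = "C" * pad + "ATG" + "GCT" * (n_codons - 2) + "TAA" + "C" * pad
            ann.add(TranscriptAnnotation(tid, seq, pad, pad + 3 * n_codons))
            vec = np.zeros(n_codons, dtype=np.int64)
            vec[1] = count
            densities[tid] = CodonDensity(tid, vec)
        return gene_counts_and_tpm(densities, ann)

    def test_equal_genes_split_evenly(self):
        q = self._quant({"A": (100, 50), "B": (100, 50)})
        assert list(q["tpm"]) == [500_000.0, 500_000.0]

    def test_length_normalization_worked_example(self):
        """100 counts/100 codons vs 100 counts/400 codons -> 800k vs 200k."""
        q = self._quant({"A": (100, 100), "B": (100, 400)})
        assert q.set_index("transcript_id")["tpm"]["A"] == 800_000.0
        assert q.set_index("transcript_id")["tpm"]["B"] == 200_000.0

    def test_single_expressed_gene_takes_all(self):
        q = self._quant({"A": (5, 100), "B": (0, 100)})
        assert q.set_index("transcript_id")["tpm"]["A"] == 1_000_000.0
        assert q.set_index("transcript_id")["tpm"]["B"] == 0.0

    def test_tpm_sums_to_one_million(self, sim_small):
        spec, ann, res, _ = sim_small
        fps, _ = filter_alignments(res.bam_path, ann, 10, 50)
        grids = build_ribogrid(fps, ann, 10, 50)
        densities, _ = codon_densities_for_sample(grids, ann, spec.offsets)
        q = gene_counts_and_tpm(densities, ann)
        assert abs(q["tpm"].sum() - 1e6) < 1e6 * 1e-6
        assert ((q["tpm"] == 0) == (q["count"] == 0)).all()

    def test_all_zero_sample_flagged_not_nan(self):
        q = self._quant({"A": (0, 100), "B": (0, 200)})
        assert q["degenerate"].all()
        assert (q["tpm"] == 0).all()
        assert not q["tpm"].isna().any()

    def test_join_count_matrix(self):
        qa = self._quant({"A": (10, 50), "B": (0, 50)})
        qb = self._quant({"A": (3, 50), "B": (7, 50)})
        mat = join_count_matrix({"s1": qa, "s2": qb})
        assert mat.loc["B", "s1"] == 0 and mat.loc["B", "s2"] == 7
        assert mat.dtypes.unique().tolist() == [np.dtype("int64")]


class TestCodonFeatureCorrelation:
    def test_constant_feature_is_degenerate(self, sim_small):
        spec, ann, res, _ = sim_small
        fps, _ = filter_alignments(res.bam_path, ann, 10, 50)
        grids = build_ribogrid(fps, ann, 10, 50)
        densities, _ = codon_densities_for_sample(grids, ann, spec.offsets)
        corr = codon_feature_correlation(
            densities, ann, {c: 1.0 for c in SENSE_CODONS}, min_reads=1
        )
        assert corr.degenerate and corr.rho == 0.0

    def test_missing_codons_rejected(self, sim_small):
        spec, ann, res, _ = sim_small
        fps, _ = filter_alignments(res.bam_path, ann, 10, 50)
        grids = build_ribogrid(fps, ann, 10, 50)
        densities, _ = codon_densities_for_sample(grids, ann, spec.offsets)
        feature = {c: 1.0 for c in SENSE_CODONS[:-3]}
        with pytest.raises(SummaryError, match="missing"):
            codon_feature_correlation(densities, ann, feature)

    def test_no_qualifying_gene_rejected(self):
        ann = single_gene_annotation()
        densities = {"T1": CodonDensity("T1", np.zeros(20, dtype=np.int64))}
        with pytest.raises(SummaryError, match="min_reads"):
            codon_feature_correlation(
                densities, ann, {c: 1.0 for c in SENSE_CODONS}, min_reads=64
            )
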