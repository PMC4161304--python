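"""Frame matching, IBD-run detection, projection and KNN filling."""

import numpy as np
import pandas as pd
import pytest

from adgwas import impute as imp
from adgwas import simul
from adgwas.model import MISSING
from conftest import build_matrix


def _panels(chip_calls, dense_calls, chip_pos, dense_pos,
            chip_alleles=None, dense_alleles=None):
    chip = build_matrix(chip_calls, positions=chip_pos,
                        alleles=chip_alleles,
                        line_ids=[f"T{i}" for i in range(len(chip_calls))])
    dense = build_matrix(dense_calls, positions=dense_pos,
                         alleles=dense_alleles,
                         line_ids=[f"D{i}" for i in range(len(dense_calls))])
    return chip, dense


class TestFrameMarkers:
    def test_identical_maps_full_overlap(self):
        chip, dense = _panels([[0, 2]], [[0, 2]], [100, 200], [100, 200])
        frame = imp.match_frame_markers(chip, dense)
        assert len(frame) == 2 and not frame.flip.any()

    def test_swapped_alleles_flip_codes(self):
        chip, dense = _panels([[0]], [[0]], [100], [100],
                              chip_alleles=[("A", "C")],
                              dense_alleles=[("C", "A")])
        frame = imp.match_frame_markers(chip, dense)
        assert frame.flip[0]
        flipped = imp.frame_calls(chip, frame.chip_idx, frame.flip)
        assert flipped[0, 0] == 2

    def test_disagreeing_alleles_dropped(self):
        chip, dense = _panels([[0, 0]], [[0, 0]], [100, 200], [100, 200],
                              chip_alleles=[("A", "C"), ("A", "C")],
                              dense_alleles=[("A", "C"), ("G", "T")])
        assert len(imp.match_frame_markers(chip, dense)) == 1

    def test_zero_overlap_errors(self):
        chip, dense = _panels([[0]], [[0]], [100], [999])
        with pytest.raises(ValueError, match="no frame markers"):
            imp.match_frame_markers(chip, dense)

    def test_constructed_partial_overlap_count(self):
        rng = np.random.default_rng(0)
        chip_pos = sorted(rng.choice(10_000, 400, replace=False) * 100 + 100)
        dense_pos = sorted(rng.choice(10_000, 400, replace=False) * 100 + 100)
        shared = len(set(chip_pos) & set(dense_pos))
        chip, dense = _panels([[0] * 400], [[0] * 400],
                              list(chip_pos), list(dense_pos))
        assert len(imp.match_frame_markers(chip, dense)) == shared


class TestIBDDetection:
    def _frame(self, n, spacing=30_000):
        pos = np.arange(1, n + 1) * spacing
        return imp.FrameMarkerSet(chip_idx=np.arange(n),
                                  dense_idx=np.arange(n),
                                  flip=np.zeros(n, bool),
                                  chrom=np.array(["1"] * n),
                                  pos_bp=pos)

    def test_exact_copy_one_segment(self):
        frame = self._frame(200)
        t = np.tile([0, 2], 100).astype(np.int8)
        segs = imp.detect_ibd_segments(t, t.copy(), frame, min_snps=150,
                                       min_span_bp=5_000_000)
        assert len(segs) == 1
        assert segs[0].n_identical == 200
        assert segs[0].start_bp == 30_000 and segs[0].end_bp == 6_000_000

    def test_run_of_149_rejected(self):
        frame = self._frame(200, spacing=50_000)
        t = np.tile([0, 2], 100).astype(np.int8)
        d = t.copy()
        d[149] = 2 - d[149]   # mismatch truncates the run at 149 markers
        segs = imp.detect_ibd_segments(t, d, frame, min_snps=150,
                                       min_span_bp=1)
        assert all(s.n_identical < 150 for s in segs)
        segs150 = imp.detect_ibd_segments(t, d, frame, min_snps=149,
                                          min_span_bp=1)
        assert any(s.n_identical == 149 for s in segs150)

    def test_missing_neither_breaks_nor_counts(self):
        frame = self._frame(10, spacing=1_000_000)
        t = np.zeros(10, np.int8)
        d = np.zeros(10, np.int8)
        d[4] = MISSING
        segs = imp.detect_ibd_segments(t, d, frame, min_snps=9, min_span_bp=1)
        assert len(segs) == 1 and segs[0].n_identical == 9
        assert imp.detect_ibd_segments(t, d, frame, min_snps=10,
                                       min_span_bp=1) == []

    def test_span_threshold_closed_interval(self):
        frame = self._frame(150, spacing=10_000)   # span 1.49 Mb
        t = np.zeros(150, np.int8)
        assert imp.detect_ibd_segments(t, t.copy(), frame, min_snps=100,
                                       min_span_bp=1_490_000 + 1) == []
        assert len(imp.detect_ibd_segments(t, t.copy(), frame, min_snps=100,
                                           min_span_bp=1_490_000)) == 1

    def test_planted_breakpoints_recovered_within_one_frame_marker(self):
        """On planted-mosaic targets, the detected run of the left-hand
        donor ends exactly at the last frame marker before the planted
        breakpoint (the generator forces the flanking frame markers to
        disagree between the two donors, so the boundary is identifiable)."""
        chip, dense, truth, bps = simul.simulate_mosaic_panel(
            seed=3, snps_per_chrom=500)
        frame = imp.match_frame_markers(chip, dense)
        chip_f = imp.frame_calls(chip, frame.chip_idx, frame.flip)
        dense_f = dense.calls[:, frame.dense_idx]
        frame_cols = frame.dense_idx  # global SNP index of each frame marker
        # left planted-segment start = previous cut on the same (target,
        # chromosome), or the chromosome start
        cuts_by_tc = {}
        for tname, chrom, cut, dl, dr in bps:
            cuts_by_tc.setdefault((tname, chrom), []).append(cut)
        checked = 0
        for tname, chrom, cut, dl, dr in bps:
            prior = [c for c in cuts_by_tc[(tname, chrom)] if c < cut]
            seg_start = max(prior) if prior else (int(chrom) - 1) * 500
            n_frame_inside = int(((frame.chrom == chrom)
                                  & (frame_cols >= seg_start)
                                  & (frame_cols < cut)).sum())
            if n_frame_inside < 30:
                continue   # planted segment too short for the thresholds
            t_i = chip.line_ids.index(tname)
            segs = imp.detect_ibd_segments(
                chip_f[t_i], dense_f[dl], frame, min_snps=25,
                min_span_bp=500_000, donor_line=dense.line_ids[dl])
            last_left_idx = np.flatnonzero((frame.chrom == chrom)
                                           & (frame_cols < cut))[-1]
            # a detected run must end exactly at the last frame marker
            # before the cut, and none may cross the planted boundary
            assert any(s.chrom == chrom and s.last_marker == last_left_idx
                       for s in segs)
            for s in segs:
                if s.chrom == chrom and s.first_marker <= last_left_idx:
                    assert s.last_marker <= last_left_idx
            checked += 1
        assert checked >= 5  # enough planted breakpoints were long enough


class TestProjection:
    def _dense(self):
        rng = np.random.default_rng(1)
        calls = rng.choice([0, 2], size=(2, 100)).astype(np.int8)
        return build_matrix(calls, positions=list(range(100, 10_100, 100)),
                            line_ids=["D0", "D1"])

    def test_full_segment_copies_donor(self):
        dense = self._dense()
        target = np.full(100, MISSING, dtype=np.int8)
        seg = imp.IBDSegment("T", "D0", "1", 0, 99, 100, 10_000, 100)
        out, mask, prov = imp.project_from_ibd(target, dense, [seg])
        np.testing.assert_array_equal(out, dense.calls[0])
        assert mask.all() and (prov == 0).all()

    def test_no_segments_no_change(self):
        dense = self._dense()
        target = np.full(100, MISSING, dtype=np.int8)
        out, mask, _ = imp.project_from_ibd(target, dense, [])
        assert (out == MISSING).all() and not mask.any()

    def test_longer_segment_wins_overlap(self):
        dense = self._dense()
        target = np.full(100, MISSING, dtype=np.int8)
        short = imp.IBDSegment("T", "D0", "1", 0, 49, 100, 5_000, 50)
        long = imp.IBDSegment("T", "D1", "1", 0, 99, 100, 10_000, 100)
        out, _, prov = imp.project_from_ibd(target, dense, [short, long])
        np.testing.assert_array_equal(out, dense.calls[1])
        assert (prov == 1).all()

    def test_observed_calls_never_overwritten(self):
        dense = self._dense()
        target = np.full(100, MISSING, dtype=np.int8)
        target[10] = 1
        seg = imp.IBDSegment("T", "D0", "1", 0, 99, 100, 10_000, 100)
        out, mask, _ = imp.project_from_ibd(target, dense, [seg])
        assert out[10] == 1 and not mask[10]


class TestKNN:
    def test_duplicate_line_exact_match_shortcut(self):
        rng = np.random.default_rng(2)
        calls = rng.choice([0, 2], size=(6, 60)).astype(np.int8)
        calls[5] = calls[0]
        calls[0, 30] = MISSING
        g = build_matrix(calls, positions=list(range(100, 6_100, 100)))
        filled = imp.knn_impute(g.calls, g.snps, imp.KNNParams(w=10, k=3))
        assert filled[0, 30] == calls[5, 30]

    def test_majority_vote_at_equal_distance(self):
        # three donors at equal distance, votes 2:1 for code 0
        calls = np.array([
            [0, MISSING, 0],
            [0, 0, 0],
            [0, 0, 0],
            [0, 2, 0],
        ], dtype=np.int8)
        snps = build_matrix(calls, positions=[100, 200, 300]).snps
        filled = imp.knn_impute(calls, snps, imp.KNNParams(w=2, k=3))
        assert filled[0, 1] == 0

    def test_no_eligible_neighbor_stays_missing(self):
        calls = np.array([[0, MISSING], [MISSING, MISSING]], dtype=np.int8)
        snps = build_matrix(calls, positions=[100, 200]).snps
        filled = imp.knn_impute(calls, snps, imp.KNNParams(w=2, k=2))
        assert filled[0, 1] == MISSING

    def test_masking_beats_major_allele_baseline(self):
        # haplotype-sharing panel: donors plus their mosaic descendants
        chip, dense, truth, _ = simul.simulate_mosaic_panel(
            n_donors=6, n_targets=8, snps_per_chrom=300, n_chrom=1, seed=9)
        stacked = build_matrix(
            np.vstack([dense.calls, truth]),
            positions=dense.snps["pos_bp"].tolist(),
            chroms=dense.snps["chrom"].tolist(),
            line_ids=dense.line_ids + chip.line_ids)
        acc, cov, baseline = imp.mask_and_score(
            stacked, fraction=0.1, seed=5, knn_params=imp.KNNParams(w=10, k=5))
        assert cov > 0.95
        assert acc > baseline


@pytest.fixture(scope="module")
def mosaic():
    return simul.simulate_mosaic_panel(seed=4)


class TestTwoStep:

    def test_accuracy_and_coverage_on_planted_mosaics(self, mosaic):
        chip, dense, truth, _ = mosaic
        completed, report = imp.two_step_impute(
            chip, dense, min_snps=30, min_span_bp=1_500_000, truth=truth)
        assert report.accuracy >= 0.99
        assert report.coverage_total > report.coverage_ibd
        assert completed.n_lines == dense.n_lines + chip.n_lines

    def test_projection_never_changes_observed(self, mosaic):
        chip, dense, truth, _ = mosaic
        completed, _ = imp.two_step_impute(
            chip, dense, min_snps=30, min_span_bp=1_500_000)
        frame = imp.match_frame_markers(chip, dense)
        chip_f = imp.frame_calls(chip, frame.chip_idx, frame.flip)
        for t_i, lid in enumerate(chip.line_ids):
            row = completed.calls[completed.line_ids.index(lid)]
            np.testing.assert_array_equal(row[frame.dense_idx], chip_f[t_i])

    def test_coverage_monotone_in_min_snps(self, mosaic):
        chip, dense, truth, _ = mosaic
        _, loose = imp.two_step_impute(chip, dense, min_snps=20,
                                       min_span_bp=500_000)
        _, strict = imp.two_step_impute(chip, dense, min_snps=60,
                                        min_span_bp=3_000_000)
        assert strict.coverage_ibd <= loose.coverage_ibd

    def test_empty_target_set_noop(self):
        rng = np.random.default_rng(6)
        calls = rng.choice([0, 2], size=(4, 50)).astype(np.int8)
        dense = build_matrix(calls, positions=list(range(100, 5_100, 100)),
                             line_ids=[f"D{i}" for i in range(4)])
        completed, report = imp.two_step_impute(dense, dense)
        assert report.coverage_total == 0.0
        assert completed.n_lines == 4


class TestEvaluate:
    def test_all_correct(self):
        truth = np.array([[0, 2, 0]], dtype=np.int8)
        imputed = truth.copy()
        mask = np.array([[True, True, False]])
        acc, cov = imp.evaluate_imputation(truth, imputed, mask)
        assert acc == 1.0 and cov == 1.0

    def test_half_filled(self):
        truth = np.array([[0, 2]], dtype=np.int8)
        imputed = np.array([[0, MISSING]], dtype=np.int8)
        mask = np.array([[True, True]])
        acc, cov = imp.evaluate_imputation(truth, imputed, mask)
        assert cov == 0.5 and acc == 1.0

    def test_zero_filled(self):
        truth = np.array([[0]], dtype=np.int8)
        imputed = np.array([[MISSING]], dtype=np.int8)
        acc, cov = imp.evaluate_imputation(truth, imputed,
                                           np.array([[True]]))
        assert acc is None and cov == 0.0

    def test_random_fill_matches_allele_frequency_expectation(self):
        rng = np.random.default_rng(7)
        n = 20_000
        p0 = 0.7
        truth = np.where(rng.random(n) < p0, 0, 2).astype(np.int8)[None, :]
        imputed = np.where(rng.random(n) < p0, 0, 2).astype(np.int8)[None, :]
        mask = np.ones((1, n), bool)
        acc, _ = imp.evaluate_imputation(truth, imputed, mask)
        expected = p0**2 + (1 - p0) ** 2
        assert acc == pytest.approx(expected, abs=0.02)
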