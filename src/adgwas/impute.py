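"""Two-step genotype imputation: IBD-based projection then KNN filling.

Low-density ("chip") target lines are completed from high-density donor
lines in two passes.  First, long runs of identical genotypes at the frame
markers (the SNPs shared by both platforms) are treated as identity-by-
descent segments, and the donor's dense genotypes are copied into the
target across each qualifying segment (defaults: >= 150 identical
consecutive frame SNPs spanning >= 5 Mb).  Second, remaining missing cells
are filled by a k-nearest-neighbor vote in a sliding marker window
(defaults w = 20 window markers, k = 6 neighbors, distance-weight exponent
p = -7, r = 1 rounds).  Projection is conservative and accurate; KNN
recovers the coverage it leaves behind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeMatrix


# ------------------------------------------------------------ frame markers


@dataclass
class FrameMarkerSet:
    """SNPs present on both platforms, matched on (chrom, pos_bp).

    ``chip_idx``/``dense_idx`` are aligned column indices into the two
    matrices; ``flip`` marks markers whose major/minor orientation is
    swapped between platforms (chip codes must be flipped 0<->2 to agree
    with the dense coding).
    """

    chip_idx: np.ndarray
    dense_idx: np.ndarray
    flip: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray

    def __len__(self) -> int:
        return len(self.chip_idx)


def match_frame_markers(chip: GenotypeMatrix, dense: GenotypeMatrix) -> FrameMarkerSet:
    """Match markers across platforms by physical position.

    A marker whose allele pair agrees but with major/minor swapped is kept
    with a flip flag; one whose alleles disagree entirely is dropped.
    """
    key_cols = ["chrom", "pos_bp"]
    a = chip.snps.reset_index().rename(columns={"index": "ci"})
    b = dense.snps.reset_index().rename(columns={"index": "di"})
    m = a.merge(b, on=key_cols, suffixes=("_c", "_d"))
    same = ((m["allele_major_c"] == m["allele_major_d"])
            & (m["allele_minor_c"] == m["allele_minor_d"]))
    swapped = ((m["allele_major_c"] == m["allele_minor_d"])
               & (m["allele_minor_c"] == m["allele_major_d"]))
    m = m[same | swapped]
    if len(m) == 0:
        raise ValueError("no frame markers: platforms share no positions")
    m = m.sort_values(key_cols, kind="stable")
    return FrameMarkerSet(
        chip_idx=m["ci"].to_numpy(),
        dense_idx=m["di"].to_numpy(),
        flip=swapped.loc[m.index].to_numpy(),
        chrom=m["chrom"].to_numpy(),
        pos_bp=m["pos_bp"].to_numpy(),
    )


def frame_calls(g: GenotypeMatrix, idx: np.ndarray, flip: np.ndarray) -> np.ndarray:
    """Extract frame-marker calls, flipping orientation where needed."""
    calls = g.calls[:, idx].copy()
    obs = calls != MISSING
    col_flip = np.broadcast_to(flip, calls.shape)
    calls[obs & col_flip] = 2 - calls[obs & col_flip]
    return calls


# -------------------------------------------------------------- IBD runs


@dataclass
class IBDSegment:
    """One qualifying identical run between a target and a donor line."""

    target_line: str
    donor_line: str
    chrom: str
    first_marker: int       # frame-marker index (within-chromosome order)
    last_marker: int
    start_bp: int
    end_bp: int
    n_identical: int


def detect_ibd_segments(target_frame: np.ndarray, donor_frame: np.ndarray,
                        frame: FrameMarkerSet, min_snps: int = 150,
                        min_span_bp: int = 5_000_000,
                        target_line: str = "target",
                        donor_line: str = "donor") -> list[IBDSegment]:
    """Maximal runs of identical non-missing frame genotypes per chromosome.

    A single informative mismatch breaks a run; missing calls on either
    line neither break the run nor count toward ``min_snps``.  Runs below
    either threshold (identical-count or closed-interval bp span) are
    dropped.
    """
    segments = []
    for chrom in pd.unique(frame.chrom):
        sel = np.flatnonzero(frame.chrom == chrom)
        t = target_frame[sel]
        d = donor_frame[sel]
        pos = frame.pos_bp[sel]
        informative = (t != MISSING) & (d != MISSING)
        match = informative & (t == d)
        mismatch = informative & (t != d)
        start = None
        n_ident = 0
        first_inf = last_inf = None

        def flush(end_excl):
            if first_inf is None:
                return
            span = int(pos[last_inf]) - int(pos[first_inf])
            if n_ident >= min_snps and span >= min_span_bp:
                segments.append(IBDSegment(
                    target_line=target_line, donor_line=donor_line,
                    chrom=str(chrom), first_marker=int(sel[first_inf]),
                    last_marker=int(sel[last_inf]),
                    start_bp=int(pos[first_inf]), end_bp=int(pos[last_inf]),
                    n_identical=int(n_ident)))

        for j in range(len(sel)):
            if mismatch[j]:
                flush(j)
                start, n_ident, first_inf, last_inf = None, 0, None, None
            elif match[j]:
                if first_inf is None:
                    first_inf = j
                last_inf = j
                n_ident += 1
        flush(len(sel))
    return segments


def _frame_identity(target_frame: np.ndarray, donor_frame: np.ndarray) -> float:
    """Genome-wide fraction of identical calls among mutually observed
    frame markers (donor-priority tie-break)."""
    obs = (target_frame != MISSING) & (donor_frame != MISSING)
    n = obs.sum()
    return float((target_frame[obs] == donor_frame[obs]).sum() / n) if n else 0.0


def project_from_ibd(target_row: np.ndarray, dense: GenotypeMatrix,
                     segments: list[IBDSegment],
                     donor_identity: dict[str, float] | None = None):
    """Copy donor dense genotypes into the target across IBD segments.

    Overlapping segments from different donors are resolved by donor
    priority: the longer segment (bp span) wins, ties by higher genome-wide
    frame identity with the target.  Observed target calls are never
    overwritten.  Returns ``(filled_row, fill_mask, provenance)`` where
    provenance[j] is the index into ``segments`` that filled SNP j (or -1).
    """
    out = target_row.copy()
    fill_mask = np.zeros(out.size, dtype=bool)
    provenance = np.full(out.size, -1, dtype=np.int64)
    donor_identity = donor_identity or {}
    # lowest priority first so higher-priority segments overwrite
    order = sorted(
        range(len(segments)),
        key=lambda i: (segments[i].end_bp - segments[i].start_bp,
                       donor_identity.get(segments[i].donor_line, 0.0)))
    chrom_arr = dense.snps["chrom"].to_numpy()
    pos_arr = dense.snps["pos_bp"].to_numpy()
    donor_rows = {lid: r for r, lid in enumerate(dense.line_ids)}
    for si in order:
        seg = segments[si]
        cols = np.flatnonzero((chrom_arr == seg.chrom)
                              & (pos_arr >= seg.start_bp)
                              & (pos_arr <= seg.end_bp))
        donor_calls = dense.calls[donor_rows[seg.donor_line], cols]
        writable = (target_row[cols] == MISSING) & (donor_calls != MISSING)
        out[cols[writable]] = donor_calls[writable]
        fill_mask[cols[writable]] = True
        provenance[cols[writable]] = si
    return out, fill_mask, provenance


# ------------------------------------------------------------------- KNN


@dataclass
class KNNParams:
    """Sliding-window KNN vote: ``w`` window markers, ``k`` neighbors,
    distance weight ``d**p`` (``p`` negative), ``r`` refill rounds."""

    w: int = 20
    k: int = 6
    p: float = -7.0
    r: int = 1

    def __post_init__(self):
        if self.w < 2 or self.k < 1 or self.r < 1:
            raise ValueError("require w >= 2, k >= 1, r >= 1")


def knn_impute(calls: np.ndarray, snps: pd.DataFrame,
               params: KNNParams = KNNParams()) -> np.ndarray:
    """Fill missing cells by a distance-weighted k-nearest-neighbor vote.

    For each missing cell (line t, SNP s): take the ``w`` markers nearest
    to s by position on the same chromosome; the distance from t to every
    line with an observed call at s is the mismatch proportion over
    mutually non-missing window markers; the ``k`` nearest lines vote,
    weighted by ``d**p``, with exact matches (d = 0) short-circuiting to
    their own consensus.  ``r`` rounds re-run the pass on the previous
    round's output.  Cells with no eligible neighbor stay missing.
    """
    filled = calls.copy()
    chrom_arr = snps["chrom"].to_numpy()
    pos_arr = snps["pos_bp"].to_numpy()
    for _ in range(params.r):
        current = filled.copy()
        for chrom in pd.unique(chrom_arr):
            cols = np.flatnonzero(chrom_arr == chrom)
            pos = pos_arr[cols]
            sub = current[:, cols]
            new_sub = filled[:, cols]
            for jj in range(cols.size):
                missing_lines = np.flatnonzero(sub[:, jj] == MISSING)
                if missing_lines.size == 0:
                    continue
                donors = np.flatnonzero(sub[:, jj] != MISSING)
                if donors.size == 0:
                    continue
                # w nearest markers by bp distance, excluding s itself
                d_pos = np.abs(pos - pos[jj])
                d_pos[jj] = np.iinfo(np.int64).max
                nwin = min(params.w, cols.size - 1)
                if nwin < 1:
                    continue
                win = np.argpartition(d_pos, nwin - 1)[:nwin]
                W = sub[:, win]
                Wobs = W != MISSING
                for t in missing_lines:
                    mutual = Wobs[t] & Wobs[donors]
                    n_mut = mutual.sum(axis=1)
                    eligible = n_mut > 0
                    if not eligible.any():
                        continue
                    cand = donors[eligible]
                    mm = ((W[t] != W[cand]) & mutual[eligible]).sum(axis=1)
                    dist = mm / n_mut[eligible]
                    kk = min(params.k, cand.size)
                    sel = np.argpartition(dist, kk - 1)[:kk]
                    nbr, nd = cand[sel], dist[sel]
                    votes = np.zeros(3)
                    exact = nd == 0.0
                    if exact.any():
                        for c in sub[nbr[exact], jj]:
                            votes[c] += 1.0
                    else:
                        wgt = nd ** params.p
                        for c, wv in zip(sub[nbr, jj], wgt):
                            votes[c] += wv
                    new_sub[t, jj] = int(np.argmax(votes))
            filled[:, cols] = new_sub
    return filled


# ------------------------------------------------------------- two-step


@dataclass
class ImputationReport:
    """Coverage (fraction of missing cells filled) and, when truth is
    available, accuracy (fraction of filled evaluable cells correct), per
    step and per line."""

    coverage_ibd: float
    coverage_total: float
    accuracy: float | None
    per_line: pd.DataFrame
    segments: pd.DataFrame


def evaluate_imputation(truth: np.ndarray, imputed: np.ndarray,
                        mask: np.ndarray):
    """accuracy = correct / (filled and evaluable); coverage = filled/masked.

    ``mask`` marks the cells that were hidden and are evaluable against
    ``truth``.  With zero filled cells accuracy is None and coverage 0.
    """
    mask = np.asarray(mask, dtype=bool)
    filled = mask & (imputed != MISSING)
    n_filled = int(filled.sum())
    coverage = n_filled / mask.sum() if mask.sum() else 0.0
    if n_filled == 0:
        return None, float(coverage)
    acc = float((imputed[filled] == truth[filled]).sum() / n_filled)
    return acc, float(coverage)


def two_step_impute(chip: GenotypeMatrix, dense: GenotypeMatrix,
                    knn_params: KNNParams = KNNParams(),
                    min_snps: int = 150, min_span_bp: int = 5_000_000,
                    truth: np.ndarray | None = None) -> tuple[GenotypeMatrix, ImputationReport]:
    """Complete chip-only target lines on the dense platform.

    Builds the frame-marker set, projects donor genotypes across qualifying
    IBD segments, then KNN-fills the remainder.  Target lines are the chip
    lines absent from the dense panel.  ``truth`` (targets x dense SNPs,
    optional) scores accuracy over cells that were missing and got filled.
    """
    frame = match_frame_markers(chip, dense)
    chip_f = frame_calls(chip, frame.chip_idx, frame.flip)
    dense_f = dense.calls[:, frame.dense_idx]
    dense_lines = set(dense.line_ids)
    targets = [l for l in chip.line_ids if l not in dense_lines]
    n_dense_snps = dense.n_snps

    # seed the target rows on the dense map with their frame calls
    dense_key = {}
    for fi in range(len(frame)):
        dense_key[frame.dense_idx[fi]] = fi
    rows = []
    seg_records = []
    per_line = []
    total_missing = 0
    filled_ibd = 0
    filled_total = 0
    correct = 0
    evaluable = 0
    all_segments: list[list[IBDSegment]] = []
    for t_i, lid in enumerate(targets):
        ti = chip.line_ids.index(lid)
        row = np.full(n_dense_snps, MISSING, dtype=np.int8)
        for dj, fi in dense_key.items():
            row[dj] = chip_f[ti, fi]
        missing0 = row == MISSING
        total_missing += int(missing0.sum())
        segs = []
        ident = {}
        for d_i, did in enumerate(dense.line_ids):
            segs.extend(detect_ibd_segments(
                chip_f[ti], dense_f[d_i], frame, min_snps=min_snps,
                min_span_bp=min_span_bp, target_line=lid, donor_line=did))
            ident[did] = _frame_identity(chip_f[ti], dense_f[d_i])
        proj, fmask, _ = project_from_ibd(row, dense, segs, donor_identity=ident)
        filled_ibd += int(fmask.sum())
        rows.append(proj)
        all_segments.append(segs)
        for s in segs:
            seg_records.append((s.chrom, s.start_bp, s.end_bp, s.target_line,
                                s.donor_line, s.n_identical))
        per_line.append({"line_id": lid, "n_missing": int(missing0.sum()),
                         "n_ibd_filled": int(fmask.sum()),
                         "n_segments": len(segs)})

    if targets:
        stacked = np.vstack([dense.calls, np.array(rows, dtype=np.int8)])
        completed = knn_impute(stacked, dense.snps, params=knn_params)
        target_rows = completed[dense.n_lines:]
    else:
        target_rows = np.zeros((0, n_dense_snps), dtype=np.int8)

    for t_i, lid in enumerate(targets):
        ti = chip.line_ids.index(lid)
        base = np.full(n_dense_snps, MISSING, dtype=np.int8)
        for dj, fi in dense_key.items():
            base[dj] = chip_f[ti, fi]
        missing0 = base == MISSING
        now_filled = missing0 & (target_rows[t_i] != MISSING)
        filled_total += int(now_filled.sum())
        per_line[t_i]["n_filled_total"] = int(now_filled.sum())
        if truth is not None:
            ev = now_filled & (truth[t_i] != MISSING)
            evaluable += int(ev.sum())
            correct += int((target_rows[t_i][ev] == truth[t_i][ev]).sum())
            per_line[t_i]["accuracy"] = (
                float((target_rows[t_i][ev] == truth[t_i][ev]).mean())
                if ev.any() else np.nan)

    out = GenotypeMatrix([*dense.line_ids, *targets], dense.snps.copy(),
                         np.vstack([dense.calls, target_rows])
                         if targets else dense.calls.copy())
    report = ImputationReport(
        coverage_ibd=filled_ibd / total_missing if total_missing else 0.0,
        coverage_total=filled_total / total_missing if total_missing else 0.0,
        accuracy=(correct / evaluable) if evaluable else None,
        per_line=pd.DataFrame(per_line) if per_line else pd.DataFrame(),
        segments=pd.DataFrame(seg_records, columns=[
            "chrom", "start_bp", "end_bp", "target", "donor", "n_markers"]),
    )
    return out, report


def mask_and_score(dense: GenotypeMatrix, fraction: float, seed: int,
                   knn_params: KNNParams = KNNParams()) -> tuple[float, float, float]:
    """Self-masking KNN harness on a dense panel.

    Hides ``fraction`` of the observed cells, KNN-fills them, and returns
    (accuracy, coverage, major-allele-fill baseline accuracy) over the
    hidden cells.  The baseline fills every hidden cell with that SNP's
    panel-major code (0), computed in-run.
    """
    rng = np.random.default_rng(seed)
    obs = dense.calls != MISSING
    mask = obs & (rng.random(dense.calls.shape) < fraction)
    hidden = dense.calls.copy()
    hidden[mask] = MISSING
    filled = knn_impute(hidden, dense.snps, params=knn_params)
    acc, cov = evaluate_imputation(dense.calls, filled, mask)
    baseline = float((dense.calls[mask] == 0).mean())
    return acc, cov, baseline
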