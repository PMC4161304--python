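"""Structured genotype simulation, phenotype schemes, and the four-method
power/type-I comparison harness.

Genotypes follow a Balding-Nichols model: ancestral allele frequencies are
uniform on [0.05, 0.95], subpopulation frequencies are Beta-distributed
around them with drift parameter Fst, and lines are drawn homozygous (a
small residual heterozygosity mimics inbred-panel data quality).

Phenotypes come in three schemes built on the same additive skeleton of 20
causal QTNs:

* scheme 1 - normally distributed trait: subpopulation structure explains
  10% of phenotypic variance, epistasis (random disjoint SNP pairs,
  product-coded) 10%, additive QTN effects h2 (default 0.5), Gaussian
  residual fills the remainder.  QTNs split 20% major (30% of genetic
  variance) / 80% moderate (70%), each half rare (MAF 0.05-0.1) and half
  common (MAF 0.25-0.45), with larger effects on rare alleles so each QTN
  class contributes equal variance per QTN.
* scheme 2 - scheme 1 plus contamination: a random 10% of lines receive an
  extra residual of 1-6 phenotypic standard deviations (random sign),
  producing a long-tailed distribution.
* scheme 3 - a large-effect rare "background" QTN: 1 background + 3 major
  + 16 moderate QTNs with genetic-variance shares 25/20/60 renormalized to
  sum to one.

Power is the per-QTN detection frequency across replicates at each
method's own genome-wide permutation threshold, so methods are compared at
matched type-I error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (MISSING, SNP_COLUMNS, GenotypeMatrix, SubpopAssignment,
                    compute_maf, make_genotype_matrix)
from . import scan as scan_mod
from .comparators import MixedModel, kinship_matrix, lm_pvalues, subpop_covariates

RARE_WINDOW = (0.05, 0.10)
COMMON_WINDOW = (0.25, 0.45)


# ----------------------------------------------------------------- schemes


@dataclass
class SimulationScheme:
    """Layout and variance budget of one phenotype-simulation scheme."""

    scheme_id: int
    n_qtn: int = 20
    structure_pve: float = 0.10
    epistasis_pve: float = 0.10
    h2: float = 0.5
    n_epistatic_pairs: int = 10
    contamination_fraction: float = 0.10       # scheme 2 only
    outlier_sd_range: tuple = (1.0, 6.0)       # scheme 2 only
    # scheme 3 shares are printed as 25/20/60 (sum 105%); renormalized
    scheme3_shares: tuple = (0.25, 0.20, 0.60)

    def __post_init__(self):
        if self.scheme_id not in (1, 2, 3):
            raise ValueError("scheme_id must be 1, 2 or 3")
        if self.structure_pve + self.epistasis_pve + self.h2 > 1.0:
            raise ValueError("requested PVE shares exceed 1")


def scheme(scheme_id: int, **overrides) -> SimulationScheme:
    return SimulationScheme(scheme_id=scheme_id, **overrides)


# ------------------------------------------------------------- genotypes


def simulate_structured_genotypes(n_lines: int, n_snps: int,
                                  n_subpops: int = 3, fst: float = 0.1,
                                  seed: int = 0, n_chrom: int = 10,
                                  residual_het: float = 0.005,
                                  snp_spacing_bp: int = 10_000):
    """Balding-Nichols structured panel of inbred lines.

    Returns ``(GenotypeMatrix, SubpopAssignment)``; calls are coded against
    the panel-wide major allele, SNPs are laid out evenly over ``n_chrom``
    chromosomes at ``snp_spacing_bp`` spacing.  Deterministic under seed.
    """
    if not 0.0 < fst < 0.5:
        raise ValueError("fst must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    shape = (1.0 - fst) / fst
    p_sub = rng.beta(p_anc * shape, (1.0 - p_anc) * shape,
                     size=(n_subpops, n_snps))
    p_sub = np.clip(p_sub, 1e-4, 1.0 - 1e-4)
    # roughly equal subpopulation sizes
    assign = np.repeat(np.arange(n_subpops), int(np.ceil(n_lines / n_subpops)))
    assign = assign[:n_lines]
    # inbred draw: allele-1 homozygote with prob p, else allele-0 homozygote,
    # with a small residual heterozygote rate
    u = rng.random((n_lines, n_snps))
    dose = np.where(u < p_sub[assign], 2, 0).astype(np.int8)
    het = rng.random((n_lines, n_snps)) < residual_het
    dose[het] = 1
    # orient to the panel-wide major allele
    freq1 = dose.astype(float).sum(axis=0) / (2 * n_lines)
    flip = freq1 > 0.5
    dose[:, flip] = (2 - dose[:, flip]).astype(np.int8)
    per_chrom = int(np.ceil(n_snps / n_chrom))
    recs = []
    for j in range(n_snps):
        chrom = str(j // per_chrom + 1)
        pos = (j % per_chrom + 1) * snp_spacing_bp
        recs.append((f"{chrom}:{pos}", chrom, pos, "A", "B"))
    snps = pd.DataFrame(recs, columns=SNP_COLUMNS)
    line_ids = [f"L{i:04d}" for i in range(n_lines)]
    g = make_genotype_matrix(line_ids, snps, dose)
    subpops = SubpopAssignment(
        {lid: f"pop{assign[i] + 1}" for i, lid in enumerate(line_ids)})
    return g, subpops


# ------------------------------------------------------------ QTN effects


@dataclass
class QTNSpec:
    """One causal SNP: its class, MAF window, and assigned allele effect."""

    snp_index: int
    qtn_class: str           # background | major | moderate
    maf_class: str           # rare | common
    effect: float            # trait units per allele-code unit
    share: float             # nominal share of total genetic variance


def _pick(rng, pool, n, used):
    avail = [i for i in pool if i not in used]
    if len(avail) < n:
        raise ValueError(
            f"not enough eligible SNPs in MAF window (need {n}, have {len(avail)})")
    chosen = rng.choice(avail, size=n, replace=False)
    used.update(int(i) for i in chosen)
    return [int(i) for i in chosen]


def assign_qtn_effects(g: GenotypeMatrix, scheme: SimulationScheme,
                       seed: int = 0) -> list[QTNSpec]:
    """Lay out the causal QTNs and their allele effects.

    Within a class, raw effect magnitudes are proportional to
    ``1/sqrt(MAF (1-MAF))`` so rare- and common-allele QTNs contribute
    equal variance (at the window anchors MAF 0.075 vs 0.35 the effect
    ratio is sqrt(0.35*0.65 / (0.075*0.925)) ~ 1.81); each class is then
    jointly rescaled so its realized genetic-variance share matches the
    scheme's split.  Signs are random.
    """
    rng = np.random.default_rng(seed)
    maf = compute_maf(g)
    rare_pool = np.flatnonzero((maf >= RARE_WINDOW[0]) & (maf <= RARE_WINDOW[1]))
    common_pool = np.flatnonzero((maf >= COMMON_WINDOW[0]) & (maf <= COMMON_WINDOW[1]))
    used: set[int] = set()
    layout = []   # (class, maf_class, snp_index)
    if scheme.scheme_id in (1, 2):
        class_share = {"major": 0.30, "moderate": 0.70}
        for idx in _pick(rng, rare_pool, 2, used):
            layout.append(("major", "rare", idx))
        for idx in _pick(rng, common_pool, 2, used):
            layout.append(("major", "common", idx))
        for idx in _pick(rng, rare_pool, 8, used):
            layout.append(("moderate", "rare", idx))
        for idx in _pick(rng, common_pool, 8, used):
            layout.append(("moderate", "common", idx))
    else:
        s = np.asarray(scheme.scheme3_shares, dtype=float)
        s = s / s.sum()
        class_share = {"background": s[0], "major": s[1], "moderate": s[2]}
        for idx in _pick(rng, rare_pool, 1, used):
            layout.append(("background", "rare", idx))
        for idx in _pick(rng, rare_pool, 1, used):
            layout.append(("major", "rare", idx))
        for idx in _pick(rng, common_pool, 2, used):
            layout.append(("major", "common", idx))
        for idx in _pick(rng, rare_pool, 8, used):
            layout.append(("moderate", "rare", idx))
        for idx in _pick(rng, common_pool, 8, used):
            layout.append(("moderate", "common", idx))
    # raw magnitudes, then per-class variance rescale on realized genotypes
    qtns = []
    for cls in class_share:
        members = [(mc, idx) for c, mc, idx in layout if c == cls]
        raw = np.array([1.0 / np.sqrt(maf[idx] * (1.0 - maf[idx]))
                        for _, idx in members])
        signs = rng.choice([-1.0, 1.0], size=len(members))
        X = g.calls[:, [idx for _, idx in members]].astype(float)
        X[X == MISSING] = np.nan
        Xc = X - np.nanmean(X, axis=0)
        comp = np.nansum(Xc * (raw * signs), axis=1)
        v = comp.var()
        scale = np.sqrt(class_share[cls] / v) if v > 0 else 0.0
        for (mc, idx), r, sgn in zip(members, raw, signs):
            qtns.append(QTNSpec(snp_index=idx, qtn_class=cls, maf_class=mc,
                                effect=float(r * sgn * scale),
                                share=class_share[cls] / len(members)))
    return qtns


# -------------------------------------------------------------- phenotype


def _rescale(component: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale a component to an exact realized variance."""
    c = component - component.mean()
    v = c.var()
    if v <= 0:
        return np.zeros_like(c)
    return c * np.sqrt(target_var / v)


def simulate_phenotype(g: GenotypeMatrix, subpops: SubpopAssignment,
                       qtns: list[QTNSpec], scheme: SimulationScheme,
                       seed: int = 0):
    """One phenotype replicate under the scheme.

    phenotype = structure + additive + epistasis + residual, each component
    exact-rescaled to its variance budget (structure 10%, additive h2,
    epistasis 10%, residual the remainder) on a unit-variance scale; scheme
    2 then perturbs a random 10% of lines by +/- U(1, 6) phenotypic SDs.
    Returns ``(phenotype, truth)`` where truth records component vectors,
    realized variance fractions and the QTN table.
    """
    rng = np.random.default_rng(seed)
    n = g.n_lines
    groups = subpops.group_vector(g.line_ids)
    labs = np.unique(groups)
    offsets = rng.normal(size=labs.size)
    structure = _rescale(offsets[np.searchsorted(labs, groups)],
                         scheme.structure_pve)

    X = g.calls[:, [q.snp_index for q in qtns]].astype(float)
    X[X == MISSING] = np.nan
    Xc = X - np.nanmean(X, axis=0)
    Xc = np.nan_to_num(Xc)
    additive_raw = Xc @ np.array([q.effect for q in qtns])
    additive = _rescale(additive_raw, scheme.h2)

    qtn_idx = {q.snp_index for q in qtns}
    pool = np.array([j for j in range(g.n_snps) if j not in qtn_idx])
    pairs = rng.choice(pool, size=(scheme.n_epistatic_pairs, 2), replace=False)
    E = g.calls[:, pairs.ravel()].astype(float)
    E[E == MISSING] = np.nan
    Ec = np.nan_to_num(E - np.nanmean(E, axis=0))
    prod = Ec[:, 0::2] * Ec[:, 1::2]
    epi_raw = prod @ rng.normal(size=scheme.n_epistatic_pairs)
    epistasis = _rescale(epi_raw, scheme.epistasis_pve)

    resid_var = 1.0 - scheme.structure_pve - scheme.epistasis_pve - scheme.h2
    residual = _rescale(rng.normal(size=n), resid_var)

    y = structure + additive + epistasis + residual
    outliers = np.zeros(n, dtype=bool)
    if scheme.scheme_id == 2:
        n_out = int(round(scheme.contamination_fraction * n))
        idx = rng.choice(n, size=n_out, replace=False)
        lo, hi = scheme.outlier_sd_range
        shift = rng.uniform(lo, hi, size=n_out) * y.std()
        shift *= rng.choice([-1.0, 1.0], size=n_out)
        y = y.copy()
        y[idx] += shift
        outliers[idx] = True

    total = y.var()
    truth = {
        "qtns": qtns,
        "components": {"structure": structure, "additive": additive,
                       "epistasis": epistasis, "residual": residual},
        "realized_pve": {"structure": structure.var() / total,
                         "additive": additive.var() / total,
                         "epistasis": epistasis.var() / total,
                         "residual": residual.var() / total},
        "outliers": outliers,
    }
    return y, truth


# ------------------------------------------------------- mosaic panels


def simulate_mosaic_panel(n_donors: int = 8, n_targets: int = 4,
                          snps_per_chrom: int = 500, n_chrom: int = 3,
                          frame_every: int = 3, max_breakpoints: int = 2,
                          snp_spacing_bp: int = 20_000, seed: int = 0):
    """Synthetic donor panel plus planted-mosaic targets for imputation tests.

    Donors are independent fully-inbred lines (codes 0/2, allele frequency
    uniform on [0.1, 0.9] per SNP).  Each target chromosome is a mosaic of
    donor segments with up to ``max_breakpoints`` planted breakpoints; to
    keep the planted boundaries identifiable, the two donors flanking each
    breakpoint are forced to differ at the nearest frame markers on either
    side.  Targets are observed only at the frame markers (every
    ``frame_every``-th SNP) -- the low-density "chip" platform.

    Returns ``(chip, dense, truth, breakpoints)``: the chip-platform target
    matrix, the dense donor matrix, the full true target calls on the dense
    map (targets x dense SNPs), and a list of (target, chrom,
    breakpoint_snp_index, left_donor, right_donor) records.
    """
    rng = np.random.default_rng(seed)
    n_snps = snps_per_chrom * n_chrom
    freq = rng.uniform(0.1, 0.9, size=n_snps)
    donors = np.where(rng.random((n_donors, n_snps)) < freq, 2, 0).astype(np.int8)
    recs = []
    for j in range(n_snps):
        chrom = str(j // snps_per_chrom + 1)
        pos = (j % snps_per_chrom + 1) * snp_spacing_bp
        recs.append((f"{chrom}:{pos}", chrom, pos, "A", "B"))
    snp_df = pd.DataFrame(recs, columns=SNP_COLUMNS)
    frame_cols = np.arange(0, n_snps, frame_every)
    is_frame = np.zeros(n_snps, dtype=bool)
    is_frame[frame_cols] = True

    # pass 1: plan every target mosaic, then force the frame markers
    # flanking each planted breakpoint to disagree between its two donors
    # (so the boundary is identifiable); truth is built only afterwards
    plans = []       # (target, chrom, bounds, donor_seq, cuts)
    breakpoints = []
    for t in range(n_targets):
        for c in range(n_chrom):
            lo, hi = c * snps_per_chrom, (c + 1) * snps_per_chrom
            n_bp = int(rng.integers(1, max_breakpoints + 1))
            cuts = np.sort(rng.choice(
                np.arange(lo + 50, hi - 50), size=n_bp, replace=False))
            bounds = [lo, *cuts.tolist(), hi]
            donor_seq = []
            prev = -1
            for _ in range(len(bounds) - 1):
                d = int(rng.integers(n_donors))
                while d == prev:
                    d = int(rng.integers(n_donors))
                donor_seq.append(d)
                prev = d
            plans.append((t, c, bounds, donor_seq, cuts))
            for s, cut in enumerate(cuts):
                breakpoints.append((f"T{t:02d}", str(c + 1), int(cut),
                                    donor_seq[s], donor_seq[s + 1]))
    for _ in range(8):   # fix-point: a flip for one pair may re-equalize another
        dirty = False
        for t, c, bounds, donor_seq, cuts in plans:
            lo, hi = c * snps_per_chrom, (c + 1) * snps_per_chrom
            chrom_frames = frame_cols[(frame_cols >= lo) & (frame_cols < hi)]
            for s, cut in enumerate(cuts):
                dl, dr = donor_seq[s], donor_seq[s + 1]
                left = chrom_frames[chrom_frames < cut]
                right = chrom_frames[chrom_frames >= cut]
                for fcol in ([left[-1]] if left.size else []) + \
                            ([right[0]] if right.size else []):
                    if donors[dl, fcol] == donors[dr, fcol]:
                        donors[dr, fcol] = 2 - donors[dr, fcol]
                        dirty = True
        if not dirty:
            break
    truth = np.empty((n_targets, n_snps), dtype=np.int8)
    for t, c, bounds, donor_seq, cuts in plans:
        for s in range(len(bounds) - 1):
            truth[t, bounds[s]:bounds[s + 1]] = \
                donors[donor_seq[s], bounds[s]:bounds[s + 1]]

    dense = make_genotype_matrix(
        [f"D{d:02d}" for d in range(n_donors)], snp_df, donors)
    chip_calls = truth[:, frame_cols]
    chip = make_genotype_matrix(
        [f"T{t:02d}" for t in range(n_targets)],
        snp_df.iloc[frame_cols].reset_index(drop=True), chip_calls)
    return chip, dense, truth, breakpoints


# ------------------------------------------------------------ method glue


def method_pvalues(method: str, g: GenotypeMatrix, phen: np.ndarray,
                   subpops: SubpopAssignment, min_class_size: int = 10,
                   mlm_model: MixedModel | None = None) -> np.ndarray:
    """Per-SNP p-vector for one association method on one phenotype.

    ``ad`` is the two-sample A-D test on the whole panel -- the same
    allele split as ``kw``, so the two nonparametric methods differ only
    in the statistic; ``ad_subpop`` scans each subpopulation and keeps the
    per-SNP minimum p (the real-data A-D workflow); ``kw`` and ``lm`` run
    on the whole panel uncorrected; ``mlm`` corrects with Q covariates and
    kinship (pass a prebuilt :class:`MixedModel` with rotated genotypes to
    amortize the eigendecomposition across calls).
    """
    if method == "ad":
        stats_df = scan_mod.ad_scan_statistics(
            g, phen, min_class_size=min_class_size)
        return stats_df["p_ad"].to_numpy()
    if method == "ad_subpop":
        best = np.full(g.n_snps, np.nan)
        for lab in subpops.labels:
            lines = subpops.lines_in(lab)
            stats_df = scan_mod.ad_scan_statistics(
                g, phen, line_subset=lines, min_class_size=min_class_size)
            p = stats_df["p_ad"].to_numpy()
            best = np.fmin(best, p)
        return best
    if method == "kw":
        stats_df = scan_mod.ad_scan_statistics(
            g, phen, min_class_size=min_class_size)
        return stats_df["p_kw"].to_numpy()
    if method == "lm":
        return lm_pvalues(g.calls, phen)
    if method == "mlm":
        if mlm_model is None:
            mlm_model = MixedModel(
                kinship_matrix(g).values,
                subpop_covariates(subpops.group_vector(g.line_ids)))
            mlm_model.set_genotypes(g.calls)
        return mlm_model.pvalues(phen).p
    raise ValueError(f"unknown method {method!r}")


# ------------------------------------------------------------ power study


@dataclass
class PowerReport:
    """Per-method, per-QTN detection frequencies plus type-I error and the
    permutation thresholds used, at a recorded replicate count."""

    qtns: pd.DataFrame                 # one row per QTN
    detection: pd.DataFrame            # columns = methods, rows align w/ qtns
    type1_error: dict
    thresholds: dict
    n_replicates: int

    def power(self, method: str, qtn_class=None, maf_class=None) -> float:
        """Mean detection frequency over QTNs filtered by class labels."""
        mask = np.ones(len(self.qtns), dtype=bool)
        if qtn_class is not None:
            mask &= self.qtns["qtn_class"].isin(np.atleast_1d(qtn_class))
        if maf_class is not None:
            mask &= self.qtns["maf_class"].isin(np.atleast_1d(maf_class))
        return float(self.detection.loc[mask, method].mean())


def run_power_study(g: GenotypeMatrix, subpops: SubpopAssignment,
                    scheme: SimulationScheme,
                    methods=("ad", "kw", "lm", "mlm"),
                    n_replicates: int = 100, n_perm: int = 200,
                    alpha: float = 0.05, seed: int = 0,
                    min_class_size: int = 5) -> PowerReport:
    """Power and type-I error of the four methods under one scheme.

    The QTN layout is drawn once from ``seed``; each method's genome-wide
    threshold is the alpha-quantile of its minimum-p distribution over
    ``n_perm`` within-subpopulation permutations of a calibration
    phenotype; each replicate then re-simulates the phenotype and marks a
    causal SNP detected iff its own p falls below the method's threshold.
    Type-I error is the rejection rate among non-causal SNPs.
    """
    rng = np.random.default_rng(seed)
    qtns = assign_qtn_effects(g, scheme, seed=int(rng.integers(2**31)))
    groups = subpops.group_vector(g.line_ids)
    mlm_model = None
    if "mlm" in methods:
        mlm_model = MixedModel(kinship_matrix(g).values,
                               subpop_covariates(groups))
        mlm_model.set_genotypes(g.calls)

    # permutation thresholds on a calibration replicate; permutation is
    # global (unstratified), so each method's threshold reflects its own
    # pure-null minimum-p distribution and realized type-I error is free to
    # differ across methods (it is reported alongside power)
    y_cal, _ = simulate_phenotype(g, subpops, qtns, scheme,
                                  seed=int(rng.integers(2**31)))
    perm_rng = np.random.default_rng(int(rng.integers(2**31)))
    thresholds = {}
    for m in methods:
        minima = np.empty(n_perm)
        for b in range(n_perm):
            yb = y_cal[perm_rng.permutation(y_cal.size)]
            p = method_pvalues(m, g, yb, subpops,
                               min_class_size=min_class_size,
                               mlm_model=mlm_model)
            finite = p[np.isfinite(p)]
            minima[b] = finite.min() if finite.size else 1.0
        thresholds[m] = float(np.quantile(minima, alpha))

    qtn_cols = np.array([q.snp_index for q in qtns])
    causal_mask = np.zeros(g.n_snps, dtype=bool)
    causal_mask[qtn_cols] = True
    detect = {m: np.zeros(len(qtns)) for m in methods}
    fp = {m: 0.0 for m in methods}
    n_null_tested = {m: 0.0 for m in methods}
    for rep in range(n_replicates):
        y, _ = simulate_phenotype(g, subpops, qtns, scheme,
                                  seed=int(rng.integers(2**31)))
        for m in methods:
            p = method_pvalues(m, g, y, subpops,
                               min_class_size=min_class_size,
                               mlm_model=mlm_model)
            hit = p < thresholds[m]
            detect[m] += hit[qtn_cols]
            null_p = p[~causal_mask]
            finite = np.isfinite(null_p)
            fp[m] += (null_p[finite] < thresholds[m]).sum()
            n_null_tested[m] += finite.sum()

    maf = compute_maf(g)
    qtn_table = pd.DataFrame({
        "snp_index": qtn_cols,
        "snp_id": g.snps["snp_id"].to_numpy()[qtn_cols],
        "qtn_class": [q.qtn_class for q in qtns],
        "maf_class": [q.maf_class for q in qtns],
        "effect": [q.effect for q in qtns],
        "maf": maf[qtn_cols],
    })
    detection = pd.DataFrame({m: detect[m] / n_replicates for m in methods})
    type1 = {m: (fp[m] / n_null_tested[m] if n_null_tested[m] else np.nan)
             for m in methods}
    return PowerReport(qtns=qtn_table, detection=detection,
                       type1_error=type1, thresholds=thresholds,
                       n_replicates=n_replicates)


def write_power_report(report: PowerReport, path: str) -> None:
    out = report.qtns.copy()
    for m in report.detection.columns:
        out[f"power_{m}"] = report.detection[m].to_numpy()
    out.to_csv(path, sep="\t", index=False)
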