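"""Genome-wide Anderson-Darling association scan.

The scan runs the two-sample A-D test SNP by SNP inside each subpopulation
(no explicit structure correction: restricting to a subpopulation is the
structure control), applies genomic control per subpopulation, and derives
significance cutoffs either by Bonferroni correction or by within-
subpopulation permutation of the phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels
from .model import MISSING, GenotypeMatrix, SubpopAssignment
from .adtest import ad_pvalue

HET_POLICIES = ("exclude", "with_major", "with_minor")

#: reason codes emitted for untestable SNPs
SKIP_OK, SKIP_CLASS_SIZE, SKIP_DEGENERATE = 0, 1, 2


class SnpSkipped(ValueError):
    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def split_by_allele(genotype_column, phenotype, het_policy: str = "exclude",
                    min_class_size: int = 10):
    """Split phenotype values into the two allele-class samples of one SNP.

    Lines with a missing genotype or phenotype are dropped; heterozygotes
    are dropped or merged into a homozygote class per ``het_policy``.
    Raises :class:`SnpSkipped` when either class ends up below
    ``min_class_size``.
    """
    if het_policy not in HET_POLICIES:
        raise ValueError(f"het_policy must be one of {HET_POLICIES}")
    gcol = np.asarray(genotype_column)
    phen = np.asarray(phenotype, dtype=float)
    keep = (gcol != MISSING) & np.isfinite(phen)
    gcol, phen = gcol[keep], phen[keep]
    if het_policy == "with_major":
        gcol = np.where(gcol == 1, 0, gcol)
    elif het_policy == "with_minor":
        gcol = np.where(gcol == 1, 2, gcol)
    s_major = phen[gcol == 0]
    s_minor = phen[gcol == 2]
    if s_major.size == 0 or s_minor.size == 0:
        raise SnpSkipped("one class empty")
    if min(s_major.size, s_minor.size) < min_class_size:
        raise SnpSkipped("class below min_class_size")
    return s_major, s_minor


def _phen_vector(g: GenotypeMatrix, phenotype) -> np.ndarray:
    """Align a phenotype (array, Series or dict keyed by line id) with the
    matrix's line order; missing -> NaN."""
    if isinstance(phenotype, pd.Series):
        return phenotype.reindex(g.line_ids).to_numpy(dtype=float)
    if isinstance(phenotype, dict):
        return np.array([phenotype.get(l, np.nan) for l in g.line_ids], float)
    arr = np.asarray(phenotype, dtype=float)
    if arr.size != g.n_lines:
        raise ValueError("phenotype length does not match line count")
    return arr


def _kernel_tables(n_max):
    if not hasattr(_kernel_tables, "_cache") or _kernel_tables._cache[0] < n_max:
        _kernel_tables._cache = (n_max, _kernels.harmonic_tables(n_max))
    return _kernel_tables._cache[1]


def ad_scan_statistics(g: GenotypeMatrix, phenotype, line_subset=None,
                       min_class_size: int = 10) -> pd.DataFrame:
    """Batched A-D (and K-W) statistics for every SNP on a line subset.

    Returns a DataFrame with T_ad, p_ad, H_kw, p_kw, class sizes and a
    skip-reason code; untestable SNPs carry NaN p-values (never p = 1, so
    "untestable" stays distinct from "tested, null").
    """
    phen = _phen_vector(g, phenotype)
    calls = g.calls
    if line_subset is not None:
        idx = g.line_index(line_subset)
        calls = calls[idx]
        phen = phen[idx]
    h_arr, g_arr = _kernel_tables(calls.shape[0])
    out = _kernels.ad_kw_kernel(np.ascontiguousarray(calls.T), phen,
                                min_class_size, h_arr, g_arr)
    T, H = out[:, 0], out[:, 1]
    p_ad = np.full(T.size, np.nan)
    ok = np.isfinite(T)
    if ok.any():
        p_ad[ok] = ad_pvalue(T[ok], m=1)
    p_kw = np.full(H.size, np.nan)
    okh = np.isfinite(H)
    p_kw[okh] = stats.chi2.sf(H[okh], 1)
    return pd.DataFrame({
        "T_ad": T, "p_ad": p_ad, "H_kw": H, "p_kw": p_kw,
        "n_major": out[:, 2].astype(int), "n_minor": out[:, 3].astype(int),
        "skip_reason": out[:, 4].astype(int),
    })


def scan_subpopulation(g: GenotypeMatrix, phenotype, subpop_lines,
                       subpop_label: str = "all", min_class_size: int = 10,
                       warn_small: int = 20) -> pd.DataFrame:
    """One A-D test per testable SNP restricted to a subpopulation's lines."""
    import warnings

    subpop_lines = list(subpop_lines)
    if len(subpop_lines) < warn_small:
        warnings.warn(
            f"subpopulation {subpop_label!r} has only {len(subpop_lines)} "
            "lines; the scan will run but power is limited", stacklevel=2)
    st_df = ad_scan_statistics(g, phenotype, line_subset=subpop_lines,
                               min_class_size=min_class_size)
    res = pd.DataFrame({
        "snp_id": g.snps["snp_id"].to_numpy(),
        "chrom": g.snps["chrom"].to_numpy(),
        "pos_bp": g.snps["pos_bp"].to_numpy(),
        "subpop": subpop_label,
        "n_major": st_df["n_major"], "n_minor": st_df["n_minor"],
        "statistic": st_df["T_ad"], "p_raw": st_df["p_ad"],
        "skip_reason": st_df["skip_reason"],
    })
    return res


def genomic_control(p_raw, trim_top: float = 0.05):
    """Regression estimator of the genomic-control inflation factor.

    Each p-value is converted to a 1-df chi-square quantile; lambda is the
    zero-intercept least-squares slope of the sorted observed quantiles on
    the expected uniform-order-statistic quantiles, with the top
    ``trim_top`` fraction of observed values excluded so true signals do
    not lever the fit.  Deflation is never applied (lambda < 1 acts as 1).

    Returns ``(lambda_hat, p_gc)`` with NaN p-values passed through.
    """
    p_raw = np.asarray(p_raw, dtype=float)
    ok = np.isfinite(p_raw)
    if not ok.any():
        raise ValueError("all p-values missing")
    p = p_raw[ok]
    n = p.size
    obs = stats.chi2.isf(np.clip(p, 1e-300, 1.0), 1)
    order = np.argsort(obs)
    exp = stats.chi2.ppf((np.arange(1, n + 1) - 0.5) / n, 1)
    keep = slice(0, n - int(np.floor(trim_top * n)))
    o, e = obs[order][keep], exp[keep]
    lam = float((o * e).sum() / (e * e).sum())
    lam_applied = max(lam, 1.0)
    p_gc = np.full(p_raw.shape, np.nan)
    p_gc[ok] = stats.chi2.sf(obs / lam_applied, 1) if lam_applied > 1.0 else p
    return lam, p_gc


@dataclass
class ThresholdSpec:
    """Per-test cutoff alpha/n and its -log10."""

    alpha: float
    n_tests: int
    p_cut: float
    neg_log10_cut: float


def bonferroni_threshold(alpha: float, n_tests: int) -> ThresholdSpec:
    if n_tests < 1 or alpha <= 0:
        raise ValueError("need n_tests >= 1 and alpha > 0")
    p_cut = alpha / n_tests
    return ThresholdSpec(alpha=alpha, n_tests=n_tests, p_cut=p_cut,
                         neg_log10_cut=float(-np.log10(p_cut)))


def ad_scan(g: GenotypeMatrix, phenotype, subpops: SubpopAssignment,
            gc: bool = True, min_class_size: int = 10,
            min_subpop_lines: int = 2) -> pd.DataFrame:
    """Full per-subpopulation A-D scan with optional genomic control.

    Returns one record per (SNP, subpopulation): statistic, p_raw, the
    subpopulation's lambda, p_gc and -log10(p_gc).
    """
    frames = []
    for label in subpops.labels:
        lines = [l for l in subpops.lines_in(label) if l in set(g.line_ids)]
        if len(lines) < min_subpop_lines:
            continue
        res = scan_subpopulation(g, phenotype, lines, subpop_label=label,
                                 min_class_size=min_class_size)
        if gc and np.isfinite(res["p_raw"]).any():
            lam, p_gc = genomic_control(res["p_raw"].to_numpy())
            res["lambda_gc"] = lam
            res["p_gc"] = p_gc
        else:
            res["lambda_gc"] = np.nan
            res["p_gc"] = res["p_raw"]
        frames.append(res)
    if not frames:
        raise ValueError("no subpopulation had enough lines to scan")
    out = pd.concat(frames, ignore_index=True)
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p_gc"])
    return out


def _permute_within(rng: np.random.Generator, phen: np.ndarray,
                    groups: np.ndarray) -> np.ndarray:
    out = phen.copy()
    for lab in np.unique(groups):
        idx = np.flatnonzero(groups == lab)
        out[idx] = phen[rng.permutation(idx)]
    return out


def permutation_threshold(g: GenotypeMatrix, phenotype,
                          subpops: SubpopAssignment, n_perm: int = 1000,
                          alpha: float = 0.05, seed: int = 0,
                          method: str = "ad", min_class_size: int = 10,
                          mlm_model=None) -> tuple[float, np.ndarray]:
    """Genome-wide permutation cutoff for one method.

    Phenotype labels are permuted within subpopulation (respecting the
    stratified design); per permutation the genome-wide minimum p is
    recorded; the cutoff is the empirical alpha-quantile of the minima.
    Returns ``(cutoff, minima)``; the seed fully determines the output.
    """
    from .simul import method_pvalues  # late import to avoid a cycle

    rng = np.random.default_rng(seed)
    phen = _phen_vector(g, phenotype)
    groups = subpops.group_vector(g.line_ids)
    minima = np.empty(n_perm)
    for b in range(n_perm):
        yb = _permute_within(rng, phen, groups)
        p = method_pvalues(method, g, yb, subpops,
                           min_class_size=min_class_size, mlm_model=mlm_model)
        finite = p[np.isfinite(p)]
        minima[b] = finite.min() if finite.size else 1.0
    return float(np.quantile(minima, alpha)), minima


def group_loci(records: pd.DataFrame, window_bp: int = 200_000) -> pd.DataFrame:
    """Collapse significant SNPs into loci by transitive distance merging.

    Consecutive significant SNPs on the same chromosome within
    ``window_bp`` of each other join the same locus (so a chain A-B-C each
    150 kb apart is one locus at the default 200 kb window).  The locus
    peak is its minimum-p SNP.
    """
    pcol = "p_gc" if "p_gc" in records.columns else "p_raw"
    df = records.sort_values(["chrom", "pos_bp"], kind="stable")
    loci = []
    cur = None
    for _, row in df.iterrows():
        if cur is not None and row["chrom"] == cur["chrom"] \
                and row["pos_bp"] - cur["end_bp"] <= window_bp:
            cur["end_bp"] = row["pos_bp"]
            cur["n_snps"] += 1
            if row[pcol] < cur["peak_p"]:
                cur["peak_p"] = row[pcol]
                cur["peak_snp"] = row["snp_id"]
        else:
            if cur is not None:
                loci.append(cur)
            cur = {"chrom": row["chrom"], "start_bp": row["pos_bp"],
                   "end_bp": row["pos_bp"], "n_snps": 1,
                   "peak_snp": row["snp_id"], "peak_p": row[pcol]}
    if cur is not None:
        loci.append(cur)
    return pd.DataFrame(loci, columns=["chrom", "start_bp", "end_bp",
                                       "n_snps", "peak_snp", "peak_p"])
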