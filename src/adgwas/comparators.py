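"""Benchmark association methods: Kruskal-Wallis, linear model, and an
EMMAX-style mixed linear model with a VanRaden kinship.

These are the comparators the power study runs against the Anderson-Darling
scan: K-W and LM ignore population structure; the MLM corrects for it with
fixed subpopulation covariates (Q) and a random polygenic term with
covariance proportional to kinship (K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar

from .model import MISSING, GenotypeMatrix, compute_maf


# ----------------------------------------------------------- Kruskal-Wallis


def kw_test(samples) -> float:
    """Kruskal-Wallis p-value for k groups (tie-corrected H, chi2 with
    k-1 df).  Returns NaN when all pooled values are tied."""
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2 or any(s.size == 0 for s in samples):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(samples)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_denom = 1.0 - (counts**3 - counts).sum() / (N**3 - N)
    if tie_denom <= 0:
        return float("nan")
    offs = np.cumsum([0] + [s.size for s in samples])
    H = 12.0 / (N * (N + 1)) * sum(
        ranks[offs[i]:offs[i + 1]].sum() ** 2 / samples[i].size
        for i in range(len(samples))
    ) - 3.0 * (N + 1)
    H /= tie_denom
    return float(stats.chi2.sf(H, len(samples) - 1))


# ------------------------------------------------------------- linear model


def lm_test(genotype, phenotype, covariates=None) -> float:
    """OLS F-test (1 df) for the SNP term, optionally after covariates.

    Missing genotype/phenotype entries are dropped; a rank-deficient design
    (e.g. monomorphic SNP) yields NaN.
    """
    x = np.asarray(genotype, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    keep = np.isfinite(y) & (np.asarray(genotype) != MISSING)
    x, y = x[keep], y[keep]
    n = y.size
    C = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)[keep]])
    X = np.column_stack([C, x])
    if np.linalg.matrix_rank(X) < X.shape[1] or n <= X.shape[1]:
        return float("nan")
    rss_full = np.linalg.lstsq(X, y, rcond=None)[1]
    rss_red = np.linalg.lstsq(C, y, rcond=None)[1]
    rss_full = float(rss_full[0]) if rss_full.size else 0.0
    rss_red = float(rss_red[0]) if rss_red.size else 0.0
    df = n - X.shape[1]
    if rss_full <= 0:
        return 0.0
    F = (rss_red - rss_full) / (rss_full / df)
    return float(stats.f.sf(F, 1, df))


def lm_pvalues(calls: np.ndarray, phen: np.ndarray) -> np.ndarray:
    """Vectorized simple-regression p-values across SNPs.

    calls : (n_lines, n_snps) int8 dosage codes (hets count as 1);
    phen : (n_lines,) with NaN for missing.  Per-SNP missing calls are
    masked out of that SNP's sums only.
    """
    ok = np.isfinite(phen)
    X = calls[ok].astype(np.float64)
    y = phen[ok]
    M = X != MISSING
    Xm = np.where(M, X, 0.0)
    n = M.sum(axis=0).astype(float)
    Sx = Xm.sum(axis=0)
    Sy = y @ M
    Sxx = (Xm * Xm).sum(axis=0)
    Sxy = y @ Xm
    Syy = (y * y) @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        Sxx_c = Sxx - Sx * Sx / n
        Sxy_c = Sxy - Sx * Sy / n
        Syy_c = Syy - Sy * Sy / n
        df = n - 2
        denom = Sxx_c * Syy_c - Sxy_c**2
        F = Sxy_c**2 * df / denom
    p = np.full(calls.shape[1], np.nan)
    good = (Sxx_c > 1e-12) & (Syy_c > 1e-12) & (df >= 1) & (denom > 0)
    p[good] = stats.f.sf(F[good], 1, df[good])
    # perfect fit (denom == 0 with signal) -> p = 0-floor
    perfect = (Sxx_c > 1e-12) & (Syy_c > 1e-12) & (df >= 1) & (denom <= 0)
    p[perfect] = 0.0
    return p


# ------------------------------------------------------------------ kinship


@dataclass
class KinshipMatrix:
    """Lines x lines VanRaden relatedness: centered-dosage cross-product
    over sum 2 p (1-p); missing calls mean-imputed, monomorphic SNPs
    dropped."""

    values: np.ndarray
    line_ids: list[str]


def kinship_matrix(g: GenotypeMatrix) -> KinshipMatrix:
    maf = compute_maf(g)
    poly = np.nan_to_num(maf, nan=0.0) > 0.0
    X = g.calls[:, poly].astype(np.float64)
    p = maf[poly]
    miss = X == MISSING
    X = np.where(miss, 2.0 * p, X)
    W = X - 2.0 * p
    denom = float((2.0 * p * (1.0 - p)).sum())
    K = W @ W.T / denom
    return KinshipMatrix((K + K.T) / 2.0, list(g.line_ids))


# -------------------------------------------------------------- mixed model


@dataclass
class MLMFit:
    """Null-model variance components and the per-SNP Wald test results."""

    sigma_g2: float
    sigma_e2: float
    delta: float          # sigma_e2 / sigma_g2
    converged: bool
    beta: np.ndarray | None = None
    se: np.ndarray | None = None
    p: np.ndarray | None = None


class MixedModel:
    """EMMAX-style association scan.

    The polygenic variance ratio ``delta = sigma_e2/sigma_g2`` is estimated
    once by REML under the null model ``y = Q beta + u + e`` (u ~ N(0,
    sigma_g2 K)) via the eigendecomposition of K, then every SNP is tested
    by generalized least squares with those components held fixed and a
    Wald t-test on the SNP coefficient.
    """

    def __init__(self, K: np.ndarray, Q: np.ndarray | None = None):
        K = np.asarray(K, dtype=float)
        n = K.shape[0]
        S, U = eigh(K)
        self.S = np.clip(S, 0.0, None)
        self.U = U
        if Q is None:
            Q = np.ones((n, 1))
        Q = np.asarray(Q, dtype=float)
        if np.linalg.matrix_rank(Q) < Q.shape[1]:
            raise ValueError("covariate matrix Q must have full column rank")
        self.Q = Q
        self.Qt = U.T @ Q
        self._Xt = None

    # -- null REML ---------------------------------------------------------

    def _neg_reml(self, log_delta: float, yt: np.ndarray) -> float:
        delta = np.exp(log_delta)
        w = 1.0 / (self.S + delta)
        A = self.Qt.T @ (w[:, None] * self.Qt)
        qWy = self.Qt.T @ (w * yt)
        try:
            beta = np.linalg.solve(A, qWy)
        except np.linalg.LinAlgError:
            return np.inf
        r = yt - self.Qt @ beta
        rWr = float((w * r * r).sum())
        n, c = yt.size, self.Qt.shape[1]
        sign, logdetA = np.linalg.slogdet(A)
        if rWr <= 0 or sign <= 0:
            return np.inf
        return 0.5 * ((n - c) * np.log(rWr) + np.log(self.S + delta).sum()
                      + logdetA)

    def fit_null(self, y: np.ndarray) -> MLMFit:
        yt = self.U.T @ np.asarray(y, dtype=float)
        grid = np.linspace(-8.0, 8.0, 33)
        vals = np.array([self._neg_reml(ld, yt) for ld in grid])
        best = int(np.nanargmin(vals))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        res = minimize_scalar(self._neg_reml, bounds=(lo, hi), args=(yt,),
                              method="bounded")
        converged = bool(res.success) and np.isfinite(res.fun)
        log_delta = float(res.x) if converged else float(grid[best])
        delta = float(np.exp(log_delta))
        w = 1.0 / (self.S + delta)
        A = self.Qt.T @ (w[:, None] * self.Qt)
        beta = np.linalg.solve(A, self.Qt.T @ (w * yt))
        r = yt - self.Qt @ beta
        n, c = yt.size, self.Qt.shape[1]
        sigma_g2 = float((w * r * r).sum()) / (n - c)
        return MLMFit(sigma_g2=sigma_g2, sigma_e2=delta * sigma_g2,
                      delta=delta, converged=converged)

    # -- per-SNP GLS -------------------------------------------------------

    def set_genotypes(self, calls: np.ndarray) -> None:
        """Rotate (and mean-impute) the genotype matrix once for reuse
        across phenotypes/permutations.  calls: (n_lines, n_snps)."""
        X = calls.astype(np.float64)
        miss = X == MISSING
        if miss.any():
            obs = ~miss
            colmean = np.where(obs, X, 0).sum(0) / np.maximum(obs.sum(0), 1)
            X = np.where(miss, colmean, X)
        self._Xt = self.U.T @ X

    def pvalues(self, y: np.ndarray, calls: np.ndarray | None = None,
                fit: MLMFit | None = None) -> MLMFit:
        """Wald p-values for every SNP at the null variance components."""
        y = np.asarray(y, dtype=float)
        if calls is not None:
            self.set_genotypes(calls)
        if self._Xt is None:
            raise ValueError("no genotypes set")
        if fit is None:
            fit = self.fit_null(y)
        yt = self.U.T @ y
        w = 1.0 / (self.S + fit.delta)
        Qt, Xt = self.Qt, self._Xt
        n, c = yt.size, Qt.shape[1]
        A = Qt.T @ (w[:, None] * Qt)
        Ainv = np.linalg.inv(A)
        qWy = Qt.T @ (w * yt)
        qWX = Qt.T @ (w[:, None] * Xt)          # (c, p)
        xWy = (w * yt) @ Xt                     # (p,)
        xWx = (w[:, None] * Xt * Xt).sum(axis=0)
        yWy = float((w * yt * yt).sum())
        u = Ainv @ qWX
        xQx = xWx - (qWX * u).sum(axis=0)
        xQy = xWy - qWy @ u
        yQy = yWy - float(qWy @ Ainv @ qWy)
        df = n - c - 1
        p = np.full(Xt.shape[1], np.nan)
        se = np.full(Xt.shape[1], np.nan)
        beta = np.full(Xt.shape[1], np.nan)
        good = xQx > 1e-10
        beta[good] = xQy[good] / xQx[good]
        with np.errstate(invalid="ignore"):
            sigma2 = (yQy - xQy[good] ** 2 / xQx[good]) / df
        sigma2 = np.clip(sigma2, 0.0, None)
        se[good] = np.sqrt(sigma2 / xQx[good])
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta[good] / se[good]
        p[good] = 2.0 * stats.t.sf(np.abs(tstat), df)
        return MLMFit(sigma_g2=fit.sigma_g2, sigma_e2=fit.sigma_e2,
                      delta=fit.delta, converged=fit.converged,
                      beta=beta, se=se, p=p)


def subpop_covariates(subpop_labels) -> np.ndarray:
    """Intercept + drop-one indicator columns for subpopulation labels."""
    labels = np.asarray(subpop_labels)
    uniq = sorted(set(labels.tolist()))
    cols = [np.ones(labels.size)]
    for lab in uniq[1:]:
        cols.append((labels == lab).astype(float))
    return np.column_stack(cols)


def mlm_scan(g: GenotypeMatrix, phenotype, K: KinshipMatrix,
             Q: np.ndarray | None = None) -> MLMFit:
    """Convenience wrapper: per-SNP MLM over a genotype matrix."""
    model = MixedModel(K.values, Q)
    return model.pvalues(np.asarray(phenotype, dtype=float), calls=g.calls)
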