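"""The k-sample Anderson-Darling test with midrank tie adjustment.

The test compares k samples against the null hypothesis that they are drawn
from one common (unspecified) distribution.  It is rank-based, weights the
tails of the pooled empirical distribution more heavily than the
Kolmogorov-Smirnov statistic, and behaves well at small sample sizes -- the
properties that make it attractive for splitting a quantitative phenotype by
the two alleles of a SNP.

Procedure
---------
1. Pool the samples, list the L distinct values ``z(1) < ... < z(L)`` with
   multiplicities ``l_j``; form midrank counts ``B_aj`` (pooled observations
   below ``z(j)`` plus half those equal) and ``M_aij`` (the same within
   sample i).  The tie-adjusted statistic is

   ``A2_akN = (N-1)/N * sum_i 1/n_i * sum_j l_j/N
              * (N*M_aij - n_i*B_aj)^2 / (B_aj*(N-B_aj) - N*l_j/4)``

   For tie-free data the unadjusted form sums over the N-1 pooled order
   statistics with plain counts ``M_ij``.
2. Under the null ``E[A2] = k-1`` and ``Var[A2] = sigma2_N`` has the closed
   form implemented in :func:`ad_variance` (an exact finite-N expression in
   harmonic-type sums; verified here against exhaustive permutation
   enumeration).
3. Standardize: ``T = (A2 - (k-1)) / sigma_N``, with ``m = k-1``.
4. Convert T to a tail probability from the tabulated upper percentiles
   ``t_m(alpha) = b0 + b1/sqrt(m) + b2/m``, interpolating the log-odds
   ``ln(alpha/(1-alpha))`` linearly in t and extrapolating the same line
   beyond the table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from itertools import combinations

import numpy as np


class DegenerateSamplesError(ValueError):
    """All pooled observations identical (or a tie denominator is not
    positive): the statistic is undefined and the test must be skipped."""


@dataclass
class TieProfile:
    """Rank/tie summary of k pooled samples (all the statistic needs)."""

    k: int
    n_i: np.ndarray          # sample sizes, shape (k,)
    N: int                   # total observations
    z: np.ndarray            # distinct pooled values, ascending, shape (L,)
    l_j: np.ndarray          # multiplicity of z(j), shape (L,)
    B_aj: np.ndarray         # pooled count below z(j) + half count equal
    M_aij: np.ndarray        # per-sample midrank counts, shape (k, L)

    @property
    def L(self) -> int:
        return len(self.z)


def build_tie_profile(samples) -> TieProfile:
    """Compute the tie profile of ``samples`` (list of 1-d float arrays)."""
    samples = [np.asarray(s, dtype=float).ravel() for s in samples]
    k = len(samples)
    if k < 2:
        raise ValueError("need at least two samples")
    for s in samples:
        if s.size == 0:
            raise ValueError("each sample must be non-empty")
        if not np.all(np.isfinite(s)):
            raise ValueError("sample values must be finite")
    n_i = np.array([s.size for s in samples])
    pooled = np.concatenate(samples)
    N = pooled.size
    z, l_j = np.unique(pooled, return_counts=True)
    below = np.concatenate(([0], np.cumsum(l_j)[:-1]))
    B_aj = below + 0.5 * l_j
    M_aij = np.empty((k, len(z)))
    for i, s in enumerate(samples):
        lt = np.searchsorted(np.sort(s), z, side="left")
        le = np.searchsorted(np.sort(s), z, side="right")
        M_aij[i] = lt + 0.5 * (le - lt)
    return TieProfile(k=k, n_i=n_i, N=N, z=z, l_j=l_j, B_aj=B_aj, M_aij=M_aij)


def ad_statistic(profile: TieProfile, tie_adjusted: bool = True) -> float:
    """Evaluate A2_akN (midrank tie-adjusted) or A2_kN (tie-free form)."""
    N, k = profile.N, profile.k
    if tie_adjusted:
        denom = profile.B_aj * (N - profile.B_aj) - N * profile.l_j / 4.0
        if np.any(denom <= 0):
            raise DegenerateSamplesError(
                "tie denominator not positive (all pooled values identical?)"
            )
        inner = (N * profile.M_aij - profile.n_i[:, None] * profile.B_aj) ** 2
        per_sample = (profile.l_j / N * inner / denom).sum(axis=1) / profile.n_i
        return float((N - 1) / N * per_sample.sum())
    # unadjusted form: requires tie-free data; sum over j = 1..N-1
    if profile.L != N:
        raise DegenerateSamplesError("unadjusted statistic requires tie-free data")
    j = np.arange(1, N)                      # pooled ranks 1..N-1
    # midrank count -> plain "<= z(j)" count: the half-integer fraction marks
    # the sample that owns z(j) (data are tie-free here)
    frac = profile.M_aij[:, :-1] % 1.0
    M_ij = np.floor(profile.M_aij[:, :-1]) + (frac > 0)
    inner = (N * M_ij - j * profile.n_i[:, None]) ** 2
    per_sample = (inner / (j * (N - j))).sum(axis=1) / profile.n_i
    return float(per_sample.sum() / N)


@dataclass
class VarianceParts:
    """Pieces of the exact null variance of the unstandardized statistic."""

    H: float
    h: float
    g: float
    a: float
    b: float
    c: float
    d: float
    sigma2_N: float


def ad_variance(k: int, n_i) -> VarianceParts:
    """Exact null variance sigma2_N of A2 for k samples of sizes ``n_i``.

    ``sigma2_N = (a N^3 + b N^2 + c N + d) / ((N-1)(N-2)(N-3))`` where the
    coefficients are polynomials in k and the sums ``H = sum 1/n_i``,
    ``h = sum_{i<N} 1/i`` and ``g = sum_{i=1}^{N-2} sum_{j=i+1}^{N-1}
    1/((N-i) j)``.
    """
    n_i = np.asarray(n_i, dtype=float)
    N = int(n_i.sum())
    if N < 4:
        raise ValueError("variance undefined for N < 4")
    H = float((1.0 / n_i).sum())
    h = float((1.0 / np.arange(1, N)).sum())
    i = np.arange(1, N - 1)
    # g = sum_i 1/(N-i) * sum_{j=i+1}^{N-1} 1/j, via suffix sums of 1/j
    inv_j = 1.0 / np.arange(1, N)
    suffix = np.concatenate((np.cumsum(inv_j[::-1])[::-1], [0.0]))
    g = float((suffix[i] / (N - i)).sum())
    a = (4 * g - 6) * (k - 1) + (10 - 6 * g) * H
    b = (2 * g - 4) * k**2 + 8 * h * k + (2 * g - 14 * h - 4) * H - 8 * h + 4 * g - 6
    c = (6 * h + 2 * g - 2) * k**2 + (4 * h - 4 * g + 6) * k + (2 * h - 6) * H + 4 * h
    d = (2 * h + 6) * k**2 - 4 * h * k
    sigma2 = (a * N**3 + b * N**2 + c * N + d) / ((N - 1) * (N - 2) * (N - 3))
    return VarianceParts(H=H, h=h, g=g, a=a, b=b, c=c, d=d, sigma2_N=float(sigma2))


def ad_standardize(A2: float, parts: VarianceParts, k: int) -> float:
    """T = (A2 - (k-1)) / sigma_N."""
    if parts.sigma2_N <= 0:
        raise ValueError("sigma2_N must be positive")
    return (A2 - (k - 1)) / np.sqrt(parts.sigma2_N)


# ------------------------------------------------------------- p-values

P_FLOOR = 1e-300  # keeps -log10(p) finite at GWAS-scale tails


def _load_critical_coeffs():
    ref = importlib.resources.files("adgwas") / "data" / "ad_critical_values.tsv"
    rows = [r.split("\t") for r in ref.read_text().strip().splitlines()[1:]]
    arr = np.array([[float(x) for x in r] for r in rows])
    return arr[:, 0], arr[:, 1:]


_ALPHAS, _COEFFS = _load_critical_coeffs()


@dataclass
class CriticalValueModel:
    """Upper-percentile model ``t_m(alpha) = b0 + b1/sqrt(m) + b2/m`` on a
    fixed alpha grid; p-values come from the log-odds of alpha vs t line."""

    alphas: np.ndarray
    coeffs: np.ndarray  # rows aligned with alphas: (b0, b1, b2)

    def t_m(self, m: int) -> np.ndarray:
        b0, b1, b2 = self.coeffs.T
        return b0 + b1 / np.sqrt(m) + b2 / m


DEFAULT_CRITICAL_MODEL = CriticalValueModel(_ALPHAS, _COEFFS)


def ad_pvalue(T, m: int = 1, model: CriticalValueModel = DEFAULT_CRITICAL_MODEL):
    """Tail probability for the standardized statistic T at m = k-1.

    Inside the tabulated range the log-odds ``ln(alpha/(1-alpha))`` is
    interpolated linearly against ``t_m(alpha)``; beyond either end the line
    through the two most extreme tabulated points is extrapolated.  The
    result is clamped to ``(P_FLOOR, 1]``.  Vectorized over T.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    t_grid = model.t_m(m)                       # increasing with decreasing alpha
    logodds = np.log(model.alphas / (1 - model.alphas))
    T = np.asarray(T, dtype=float)
    # np.interp needs ascending x; t_grid ascends as alpha descends
    lo = np.interp(T, t_grid, logodds)
    # linear extrapolation outside the table
    left = T < t_grid[0]
    right = T > t_grid[-1]
    sl_l = (logodds[1] - logodds[0]) / (t_grid[1] - t_grid[0])
    sl_r = (logodds[-1] - logodds[-2]) / (t_grid[-1] - t_grid[-2])
    lo = np.where(left, logodds[0] + sl_l * (T - t_grid[0]), lo)
    lo = np.where(right, logodds[-1] + sl_r * (T - t_grid[-1]), lo)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-lo))
    p = np.clip(p, P_FLOOR, 1.0)
    return float(p) if p.ndim == 0 else p


@dataclass
class ADResult:
    """One A-D test: statistic, null moments, standardized T, p."""

    A2_akN: float
    sigma2_N: float
    m: int
    T: float
    p: float
    A2_kN: float | None = None


def ad_test(samples, tie_adjusted: bool = True,
            model: CriticalValueModel = DEFAULT_CRITICAL_MODEL) -> ADResult:
    """Run the full test on k samples: statistic -> variance -> T -> p."""
    profile = build_tie_profile(samples)
    A2 = ad_statistic(profile, tie_adjusted=tie_adjusted)
    parts = ad_variance(profile.k, profile.n_i)
    T = ad_standardize(A2, parts, profile.k)
    m = profile.k - 1
    return ADResult(A2_akN=A2, sigma2_N=parts.sigma2_N, m=m, T=T,
                    p=ad_pvalue(T, m, model))


# ------------------------------------------------------ exhaustive oracle


def exact_null_distribution(values, n1: int, tie_adjusted: bool = False):
    """Enumerate the exact two-sample null distribution of A2.

    Splits ``values`` every possible way into samples of size ``n1`` and
    ``N - n1`` (all C(N, n1) label assignments equally likely under the
    null) and returns a list of ``(A2, probability)`` pairs.  Combinatorial:
    refuses N > 12.  Used to verify E[A2] = k-1 and Var[A2] = sigma2_N.
    """
    values = np.asarray(values, dtype=float)
    N = values.size
    if N > 12:
        raise ValueError("exhaustive enumeration limited to N <= 12")
    if not 1 <= n1 < N:
        raise ValueError("n1 must satisfy 1 <= n1 < N")
    idx = range(N)
    out = []
    n_splits = 0
    for combo in combinations(idx, n1):
        rest = [i for i in idx if i not in combo]
        prof = build_tie_profile([values[list(combo)], values[rest]])
        out.append(ad_statistic(prof, tie_adjusted=tie_adjusted))
        n_splits += 1
    prob = 1.0 / n_splits
    return [(a2, prob) for a2 in out]
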