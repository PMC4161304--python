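"""Numba-compiled batch kernels for genome-wide scanning.

The per-SNP Anderson-Darling and Kruskal-Wallis computations share one
gather-sort-walk pass over the phenotype values split by allele; batching
them in a compiled kernel is what makes permutation thresholds and the
power study tractable.  ``tests/test_scan.py`` asserts the kernel agrees
with the pure-numpy reference in :mod:`adgwas.adtest` to 1e-10.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .model import MISSING

_MISS = MISSING


def harmonic_tables(n_max: int):
    """h[N] = sum_{i<N} 1/i and g[N] = sum_{i=1}^{N-2} sum_{j=i+1}^{N-1}
    1/((N-i) j), indexed by total sample size N (entries below 4 unused)."""
    h = np.zeros(n_max + 1)
    g = np.zeros(n_max + 1)
    inv = 1.0 / np.arange(1, n_max + 1)
    for N in range(2, n_max + 1):
        h[N] = inv[: N - 1].sum()
    for N in range(4, n_max + 1):
        suffix = np.concatenate((np.cumsum(inv[: N - 1][::-1])[::-1], [0.0]))
        i = np.arange(1, N - 1)
        g[N] = (suffix[i] / (N - i)).sum()
    return h, g


@njit(cache=True)
def ad_kw_kernel(calls_t, phen, min_class, h_arr, g_arr):  # pragma: no cover
    """Per-SNP two-sample A-D (standardized T) and K-W (H) statistics.

    calls_t : (n_snps, n_lines) int8, codes 0/1/2/missing; hets and missing
        calls are excluded from the two-class split.
    phen : (n_lines,) float64, NaN = missing phenotype.

    Returns (n_snps, 5): T_ad, H_kw, n_major, n_minor, reason
    (reason 0 = tested, 1 = a class below min_class, 2 = degenerate ties).
    Untestable entries carry NaN statistics.
    """
    n_snps, n_lines = calls_t.shape
    out = np.full((n_snps, 5), np.nan)
    vals = np.empty(n_lines)
    labs = np.empty(n_lines, np.int8)
    for s in range(n_snps):
        n = 0
        n1 = 0
        n2 = 0
        for i in range(n_lines):
            c = calls_t[s, i]
            if c == 0 or c == 2:
                y = phen[i]
                if y == y:
                    vals[n] = y
                    labs[n] = c
                    n += 1
                    if c == 0:
                        n1 += 1
                    else:
                        n2 += 1
        out[s, 2] = n1
        out[s, 3] = n2
        if n1 < min_class or n2 < min_class or n < 4:
            out[s, 4] = 1.0
            continue
        order = np.argsort(vals[:n], kind="mergesort")
        N = n
        acc1 = 0.0
        acc2 = 0.0
        R1 = 0.0
        tie3 = 0.0
        b = 0
        m1 = 0
        ok = True
        j = 0
        while j < N:
            v = vals[order[j]]
            l = 0
            e1 = 0
            while j < N and vals[order[j]] == v:
                if labs[order[j]] == 0:
                    e1 += 1
                l += 1
                j += 1
            Ba = b + 0.5 * l
            Ma1 = m1 + 0.5 * e1
            Ma2 = (b - m1) + 0.5 * (l - e1)
            denom = Ba * (N - Ba) - N * l / 4.0
            if denom <= 0.0:
                ok = False
                break
            acc1 += l * (N * Ma1 - n1 * Ba) ** 2 / denom
            acc2 += l * (N * Ma2 - n2 * Ba) ** 2 / denom
            R1 += e1 * (b + (l + 1) / 2.0)
            tie3 += l * (l * l - 1.0)
            b += l
            m1 += e1
        if not ok:
            out[s, 4] = 2.0
            continue
        A2 = (N - 1.0) / (N * N) * (acc1 / n1 + acc2 / n2)
        Hc = 1.0 / n1 + 1.0 / n2
        h = h_arr[N]
        g = g_arr[N]
        k = 2.0
        ca = (4.0 * g - 6.0) * (k - 1.0) + (10.0 - 6.0 * g) * Hc
        cb = ((2.0 * g - 4.0) * k * k + 8.0 * h * k
              + (2.0 * g - 14.0 * h - 4.0) * Hc - 8.0 * h + 4.0 * g - 6.0)
        cc = ((6.0 * h + 2.0 * g - 2.0) * k * k
              + (4.0 * h - 4.0 * g + 6.0) * k + (2.0 * h - 6.0) * Hc + 4.0 * h)
        cd = (2.0 * h + 6.0) * k * k - 4.0 * h * k
        Nf = float(N)
        sigma2 = ((ca * Nf ** 3 + cb * Nf ** 2 + cc * Nf + cd)
                  / ((Nf - 1.0) * (Nf - 2.0) * (Nf - 3.0)))
        if sigma2 <= 0.0:
            out[s, 4] = 2.0
            continue
        out[s, 0] = (A2 - 1.0) / np.sqrt(sigma2)
        # Kruskal-Wallis with tie correction on the same split
        tie_denom = 1.0 - tie3 / (Nf ** 3 - Nf)
        if tie_denom > 0.0:
            R2 = Nf * (Nf + 1.0) / 2.0 - R1
            out[s, 1] = ((12.0 / (Nf * (Nf + 1.0))
                          * (R1 * R1 / n1 + R2 * R2 / n2)
                          - 3.0 * (Nf + 1.0)) / tie_denom)
        out[s, 4] = 0.0
    return out
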