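"""Shared data model for inbred-line genotype panels.

Genotype calls are coded per SNP relative to the within-file major allele:
``0`` = major-allele homozygote, ``1`` = heterozygote, ``2`` = minor-allele
homozygote, :data:`MISSING` = no call.  Physical positions are 1-based and
intervals are closed.  All frequency denominators exclude missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.  A dedicated code, never used in
#: arithmetic: every downstream denominator masks it out explicitly.
MISSING: int = -9

SNP_COLUMNS = ["snp_id", "chrom", "pos_bp", "allele_major", "allele_minor"]


@dataclass(frozen=True)
class SnpInfo:
    """Map entry for one SNP: identifier, chromosome, 1-based bp position,
    and the major/minor allele characters the 0/2 codes refer to."""

    snp_id: str
    chrom: str
    pos_bp: int
    allele_major: str = "A"
    allele_minor: str = "B"


@dataclass
class GenotypeMatrix:
    """Lines x SNPs integer-coded genotype calls plus the per-SNP map.

    Parameters
    ----------
    line_ids
        Unique line identifiers, one per row of ``calls``.
    snps
        DataFrame with columns ``snp_id, chrom, pos_bp, allele_major,
        allele_minor``, sorted by position within each chromosome.
    calls
        ``(n_lines, n_snps)`` int8 array with entries 0/1/2/:data:`MISSING`.
    """

    line_ids: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.line_ids), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.line_ids)} lines x {len(self.snps)} SNPs"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("line ids must be unique")
        ids = self.snps["snp_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate snp_id {dup!r}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def line_index(self, ids) -> np.ndarray:
        lookup = {lid: i for i, lid in enumerate(self.line_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"unknown line id {exc.args[0]!r}") from None

    def subset_lines(self, ids) -> "GenotypeMatrix":
        idx = self.line_index(ids)
        return GenotypeMatrix(list(ids), self.snps.copy(), self.calls[idx])

    def subset_snps(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(np.intp)
        return GenotypeMatrix(
            list(self.line_ids),
            self.snps.iloc[idx].reset_index(drop=True),
            self.calls[:, idx],
        )

    def heterozygosity(self) -> np.ndarray:
        """Per-line fraction of het calls among non-missing calls."""
        obs = self.calls != MISSING
        het = self.calls == 1
        n_obs = obs.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(n_obs > 0, het.sum(axis=1) / n_obs, np.nan)


@dataclass
class PhenotypeTable:
    """line_id -> trait values; NaN marks a missing phenotype."""

    table: pd.DataFrame  # index = line_id, one column per trait

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("phenotyped line ids must be unique")

    def trait(self, name: str) -> pd.Series:
        return self.table[name]


@dataclass
class SubpopAssignment:
    """Mapping line_id -> subpopulation label (every line exactly one)."""

    mapping: dict[str, str]

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def lines_in(self, label: str) -> list[str]:
        return [l for l, g in self.mapping.items() if g == label]

    def group_vector(self, line_ids) -> np.ndarray:
        return np.array([self.mapping[l] for l in line_ids])


def compute_maf(g: GenotypeMatrix, lines_subset=None) -> np.ndarray:
    """Per-SNP minor-allele frequency: minor-allele count over 2x the
    non-missing line count.  SNPs with no non-missing call in the subset
    get NaN.

    Note the "minor" allele is fixed by the matrix coding (code 2), so the
    returned value can exceed 0.5 in a subset where the panel-wide minor
    allele is locally the commoner one.
    """
    calls = g.calls if lines_subset is None else g.calls[g.line_index(lines_subset)]
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    minor = np.where(obs, calls, 0).sum(axis=0)  # code = minor-allele dosage
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(n_obs > 0, minor / (2.0 * n_obs), np.nan)
    return maf


def filter_maf(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Keep SNPs with MAF strictly greater than ``threshold`` (in [0, 0.5])."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    maf = compute_maf(g)
    keep = np.nan_to_num(maf, nan=0.0) > threshold
    return g.subset_snps(keep)


def filter_heterozygosity(g: GenotypeMatrix, max_het: float = 0.10) -> GenotypeMatrix:
    """Drop lines whose het-call fraction exceeds ``max_het`` (panels of
    inbred lines treat high residual heterozygosity as a data-quality flag)."""
    het = g.heterozygosity()
    keep = ~(het > max_het)
    ids = [lid for lid, k in zip(g.line_ids, keep) if k]
    return g.subset_lines(ids)


def _sort_snps(snps: pd.DataFrame, calls: np.ndarray):
    order = snps.sort_values(["chrom", "pos_bp"], kind="stable").index.to_numpy()
    return snps.iloc[order].reset_index(drop=True), calls[:, order]


def make_genotype_matrix(line_ids, snps: pd.DataFrame, calls) -> GenotypeMatrix:
    """Construct a :class:`GenotypeMatrix`, sorting SNPs by (chrom, pos)."""
    snps, calls = _sort_snps(snps.reset_index(drop=True), np.asarray(calls, dtype=np.int8))
    return GenotypeMatrix(list(line_ids), snps, calls)
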