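"""Readers and writers for genotype, phenotype, subpopulation and result files.

Three genotype dialects are supported:

``tsv``
    Plain matrix: header row = ``line_id`` followed by snp ids, one line per
    row, calls coded 0/1/2 with ``NA`` for missing.  Snp ids of the form
    ``<chrom>:<pos>`` are parsed into the SNP map; any other ids are placed
    sequentially on pseudo-chromosome ``"un"``.
``hapmap``
    HapMap-format text: 11 fixed metadata columns then one two-letter
    genotype column per line (``AA``/``AG``/``NN`` ...).
``vcf``
    VCF 4.x, GT field only (read through :mod:`cyvcf2`).

All dialects code calls relative to the within-file major allele (the more
frequent allele; ties resolve to the first-listed/REF allele).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .model import (
    MISSING,
    SNP_COLUMNS,
    GenotypeMatrix,
    PhenotypeTable,
    SubpopAssignment,
    make_genotype_matrix,
)

_HAPMAP_META = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


class ParseError(ValueError):
    """Malformed record; message carries the 1-based line number."""


# ---------------------------------------------------------------- reading


def read_genotypes(path: str, format: str) -> GenotypeMatrix:
    """Read a genotype file in the named dialect into a GenotypeMatrix."""
    if format == "tsv":
        return _read_tsv(path)
    if format == "hapmap":
        return _read_hapmap(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _parse_snp_id(snp_id: str, fallback_pos: int):
    if ":" in snp_id:
        chrom, _, pos = snp_id.partition(":")
        try:
            return chrom, int(pos)
        except ValueError:
            pass
    return "un", fallback_pos


def _read_tsv(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    snp_ids = header[1:]
    if len(set(snp_ids)) != len(snp_ids):
        dup = next(s for s in snp_ids if snp_ids.count(s) > 1)
        raise ParseError(f"duplicate snp_id {dup!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    line_ids = df.iloc[:, 0].tolist()
    calls = np.full((len(line_ids), len(snp_ids)), MISSING, dtype=np.int8)
    body = df.iloc[:, 1:].to_numpy()
    for j in range(body.shape[1]):
        for i in range(body.shape[0]):
            v = body[i, j]
            if v == "NA" or v == "":
                continue
            if v not in ("0", "1", "2"):
                raise ParseError(f"line {i + 2}: bad call {v!r} for SNP {snp_ids[j]}")
            calls[i, j] = int(v)
    snps = pd.DataFrame(
        [
            (sid, *_parse_snp_id(sid, j + 1), "A", "B")
            for j, sid in enumerate(snp_ids)
        ],
        columns=SNP_COLUMNS,
    )
    return make_genotype_matrix(line_ids, snps, calls)


def _read_hapmap(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 12:
            raise ParseError("line 1: HapMap header needs 11 metadata columns + calls")
        line_ids = header[11:]
        rows, recs = [], []
        for ln, raw in enumerate(fh, start=2):
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != 11 + len(line_ids):
                raise ParseError(f"line {ln}: expected {11 + len(line_ids)} fields")
            snp_id, alleles, chrom, pos = fields[0], fields[1], fields[2], fields[3]
            try:
                pos = int(pos)
            except ValueError:
                raise ParseError(f"line {ln}: bad position {fields[3]!r}") from None
            a1, _, a2 = alleles.partition("/")
            genos = fields[11:]
            # count alleles to orient coding to the within-file major allele
            n1 = sum(g.count(a1) for g in genos if g != "NN")
            n2 = sum(g.count(a2) for g in genos if g != "NN")
            major, minor = (a1, a2) if n1 >= n2 else (a2, a1)
            row = np.full(len(line_ids), MISSING, dtype=np.int8)
            for i, g in enumerate(genos):
                if g == "NN" or g == "N":
                    continue
                row[i] = sum(ch == minor for ch in g)
            rows.append(row)
            recs.append((snp_id, chrom, pos, major, minor))
    snps = pd.DataFrame(recs, columns=SNP_COLUMNS)
    return make_genotype_matrix(line_ids, snps, np.array(rows, dtype=np.int8).T)


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    line_ids = list(vcf.samples)
    rows, recs = [], []
    seen = set()
    for var in vcf:
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        if snp_id in seen:
            raise ParseError(f"duplicate snp_id {snp_id!r}")
        seen.add(snp_id)
        ref, alt = var.REF, (var.ALT[0] if var.ALT else ".")
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (cyvcf2 gts012), 3=missing
        vcf_codes = np.asarray(var.gt_types)
        alt_dose = np.where(vcf_codes == 3, MISSING, vcf_codes).astype(np.int8)
        obs = alt_dose != MISSING
        n_alt = int(alt_dose[obs].sum())
        n_ref = int(2 * obs.sum() - n_alt)
        if n_alt > n_ref:  # ALT is the major allele: flip coding
            major, minor = alt, ref
            row = np.where(obs, 2 - alt_dose, MISSING).astype(np.int8)
        else:
            major, minor = ref, alt
            row = alt_dose
        rows.append(row)
        recs.append((snp_id, var.CHROM, var.POS, major, minor))
    snps = pd.DataFrame(recs, columns=SNP_COLUMNS)
    return make_genotype_matrix(line_ids, snps, np.array(rows, dtype=np.int8).T)


# ---------------------------------------------------------------- writing


def write_genotypes(g: GenotypeMatrix, path: str, format: str) -> None:
    if format == "tsv":
        _write_tsv(g, path)
    elif format == "hapmap":
        _write_hapmap(g, path)
    elif format == "vcf":
        _write_vcf(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _write_tsv(g: GenotypeMatrix, path: str) -> None:
    body = g.calls.astype(object)
    body[g.calls == MISSING] = "NA"
    df = pd.DataFrame(body, columns=g.snps["snp_id"].tolist())
    df.insert(0, "line_id", g.line_ids)
    df.to_csv(path, sep="\t", index=False)


def _write_hapmap(g: GenotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_META + g.line_ids) + "\n")
        for j, snp in g.snps.iterrows():
            maj, mnr = snp["allele_major"], snp["allele_minor"]
            geno = []
            for c in g.calls[:, j]:
                if c == MISSING:
                    geno.append("NN")
                else:
                    geno.append({0: maj + maj, 1: maj + mnr, 2: mnr + mnr}[int(c)])
            meta = [snp["snp_id"], f"{maj}/{mnr}", snp["chrom"], str(snp["pos_bp"]),
                    "+", "NA", "NA", "NA", "NA", "NA", "NA"]
            fh.write("\t".join(meta + geno) + "\n")


def _write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Minimal plain-text VCF 4.2 emitter (REF = major allele, GT only)."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in g.snps["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.line_ids) + "\n")
        for j, snp in g.snps.iterrows():
            cells = [gt[int(c)] for c in g.calls[:, j]]
            fh.write("\t".join(
                [snp["chrom"], str(snp["pos_bp"]), snp["snp_id"],
                 snp["allele_major"], snp["allele_minor"], ".", "PASS", ".", "GT"]
                + cells) + "\n")


# ------------------------------------------------- phenotypes & subpops


def read_phenotypes(path: str) -> PhenotypeTable:
    """2+ column TSV: line_id then one column per trait, NA for missing."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], index_col=0)
    return PhenotypeTable(df)


def write_phenotypes(p: PhenotypeTable, path: str) -> None:
    p.table.to_csv(path, sep="\t", na_rep="NA")


def read_subpops(path: str) -> SubpopAssignment:
    """2-column TSV: line_id, subpopulation label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SubpopAssignment(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_subpops(s: SubpopAssignment, path: str) -> None:
    pd.DataFrame(
        {"line_id": list(s.mapping), "subpop": list(s.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- results


def write_scan_results(results: pd.DataFrame, path: str) -> None:
    """Write per-SNP, per-subpopulation association records as TSV.

    Columns: snp_id, chrom, pos_bp, subpop, statistic, p_raw, p_gc,
    neg_log10_p; rows sorted by (chrom, pos_bp, subpop); missing p -> "NA".
    """
    if len(results) == 0:
        raise ValueError("no scan results to write")
    cols = ["snp_id", "chrom", "pos_bp", "subpop", "statistic",
            "p_raw", "p_gc", "neg_log10_p"]
    out = results[cols].sort_values(
        ["chrom", "pos_bp", "subpop"], kind="stable"
    )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_scan_results(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["chrom"] = df["chrom"].astype(str)
    return df


def ensure_dir(path: str) -> None:
    os.makedirs(path, exist_ok=True)
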