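"""Readers and writers for the pipeline's interchange formats.

Conventions: positions are 1-based inclusive everywhere inside the package;
the BED writer converts to 0-based half-open at the boundary.  Pool-count
tables travel as headered TSV (the native schema) or as VCF with two pool
samples named U and M carrying allele-depth (AD) fields.  All writers are
deterministic: fixed column order, fixed float formatting, no timestamps.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pysam

from .bsa_scan import REGION_COLUMNS, SCAN_COLUMNS
from .enrichment import RESULT_COLUMNS
from .synthetic_cross import COUNTS_COLUMNS

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------- pool counts

def read_pool_counts(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a two-pool SNP allele-count table (TSV or VCF).

    ``fmt`` is inferred from the extension when omitted.  Output schema is
    the synthetic generator's: chrom, pos, ref, alt, refU, altU, refM,
    altM (+ alt_origin when present), sorted by (chrom, pos).
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() in {".vcf", ".bcf"} or str(path).endswith(".vcf.gz") else "tsv"
    if fmt == "tsv":
        df = _read_pool_counts_tsv(path)
    elif fmt == "vcf":
        df = _read_pool_counts_vcf(path)
    else:
        raise ValueError(f"unknown pool-counts format {fmt!r}")
    return _validate_pool_counts(df)


def _validate_pool_counts(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        logger.warning("pool-counts table is empty")
        cols = [c for c in COUNTS_COLUMNS if c in df.columns or c != "alt_origin"]
        return pd.DataFrame(columns=cols)
    for col in ("refU", "altU", "refM", "altM"):
        if (df[col] < 0).any():
            raise ValueError(f"negative counts in column {col}")
    if (df["pos"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return df


def _read_pool_counts_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "refU", "altU", "refM", "altM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        return df
    for i, (col, dtype) in enumerate(df.dtypes.items()):
        if col in ("pos", "refU", "altU", "refM", "altM") and not np.issubdtype(dtype, np.integer):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            line = bad.index[0] + 2 if len(bad) else "?"
            raise ValueError(f"{path}: non-integer value in column {col} near line {line}")
    return df


def _read_pool_counts_vcf(path: Path) -> pd.DataFrame:
    rows = []
    n_multiallelic = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 2:
            raise ValueError(
                f"{path}: expected exactly two pool samples, found {samples}"
            )
        # prefer samples named U/M; otherwise first = U, second = M
        if set(samples) == {"U", "M"}:
            s_u, s_m = "U", "M"
        else:
            s_u, s_m = samples
            logger.warning("VCF samples %s: treating %s as pool U, %s as pool M",
                           samples, s_u, s_m)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_multiallelic += 1
                continue
            try:
                ad_u = rec.samples[s_u]["AD"]
                ad_m = rec.samples[s_m]["AD"]
            except KeyError:
                raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} lacks AD fields")
            if ad_u is None or ad_m is None or len(ad_u) != 2 or len(ad_m) != 2:
                raise ValueError(f"{path}: malformed AD at {rec.chrom}:{rec.pos}")
            rows.append((rec.chrom, rec.pos, rec.ref, rec.alts[0],
                         int(ad_u[0]), int(ad_u[1]), int(ad_m[0]), int(ad_m[1])))
    if n_multiallelic:
        logger.info("read_pool_counts: skipped %d multi-allelic records", n_multiallelic)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                     "refU", "altU", "refM", "altM"])
    df.attrs["n_multiallelic_skipped"] = n_multiallelic
    return df


def write_pool_counts(df: pd.DataFrame, path, fmt: str | None = None,
                      contig_lengths: dict[str, int] | None = None) -> None:
    """Write a pool-count table as TSV or as a two-sample VCF with AD."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "tsv":
        cols = [c for c in COUNTS_COLUMNS if c in df.columns]
        df[cols].to_csv(path, sep="\t", index=False)
        return
    if fmt != "vcf":
        raise ValueError(f"unknown pool-counts format {fmt!r}")
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                    'Description="Allelic depths for the ref and alt alleles">')
    chroms = list(dict.fromkeys(df["chrom"].astype(str)))
    for chrom in chroms:
        length = (contig_lengths or {}).get(chrom)
        if length is None:
            length = int(df.loc[df["chrom"].astype(str) == chrom, "pos"].max()) + 1
        header.contigs.add(chrom, length=length)
    header.add_sample("U")
    header.add_sample("M")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in df.itertuples(index=False):
            rec = out.new_record(
                contig=str(row.chrom), start=int(row.pos) - 1,
                alleles=(str(getattr(row, "ref", "A")), str(getattr(row, "alt", "C"))),
            )
            rec.samples["U"]["AD"] = (int(row.refU), int(row.altU))
            rec.samples["M"]["AD"] = (int(row.refM), int(row.altM))
            out.write(rec)


# ------------------------------------------------------------- scan & regions

def write_scan(scan_df: pd.DataFrame, path) -> None:
    scan_df[SCAN_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_scan(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SCAN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing scan columns {sorted(missing)}")
    return df


def write_regions(regions: pd.DataFrame, path) -> None:
    """Write candidate regions as BED (0-based half-open).

    Columns: chrom, start, end, name (region_<i>), score (peak log odds),
    then peak_pos (1-based) and n_snps as extra fields.
    """
    with open(path, "w") as fh:
        for i, row in enumerate(regions.itertuples(index=False), start=1):
            fh.write(
                f"{row.chrom}\t{int(row.start) - 1}\t{int(row.end)}\t"
                f"region_{i}\t{row.peak_log_odds:.6g}\t{int(row.peak_pos)}\t{int(row.n_snps)}\n"
            )


def read_regions(path) -> pd.DataFrame:
    """Read the BED emitted by :func:`write_regions` back to 1-based form."""
    names = ["chrom", "bed_start", "end", "name", "peak_log_odds", "peak_pos", "n_snps"]
    df = pd.read_csv(path, sep="\t", header=None, names=names, dtype={"chrom": str})
    if df.empty:
        return pd.DataFrame(columns=REGION_COLUMNS)
    df["start"] = df["bed_start"].astype(int) + 1
    return df[REGION_COLUMNS]


# --------------------------------------------------------------- other tables

def write_enrichment(results: pd.DataFrame, path) -> None:
    results[RESULT_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_enrichment(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_fpkm(path) -> pd.DataFrame:
    """Gene x sample FPKM table; first column = gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def read_gene_list(path) -> list[str]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_hits(path) -> pd.DataFrame:
    """Homology hits from outfmt-6-style TSV.

    Accepts either a headered table with columns (query, subject, taxon,
    evalue) or a headerless 4-column ``qseqid sseqid evalue staxids``
    layout.
    """
    first = pd.read_csv(path, sep="\t", nrows=1, header=None, dtype=str)
    headered = set(first.iloc[0]) >= {"query", "subject", "evalue"}
    if headered:
        df = pd.read_csv(path, sep="\t", dtype={"query": str, "subject": str, "taxon": str})
    else:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["query", "subject", "evalue", "taxon"],
                         dtype={"query": str, "subject": str, "taxon": str})
        df = df[["query", "subject", "taxon", "evalue"]]
    df["evalue"] = pd.to_numeric(df["evalue"], errors="raise")
    return df


def read_annotations(path) -> dict[str, set]:
    """Two-column (gene, category) TSV -> category -> gene-set mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "category"],
                     dtype=str, comment="#")
    return {cat: set(sub["gene"]) for cat, sub in df.groupby("category")}


def write_de_sets(de_set, path) -> None:
    """Long-format DE table (gene, time, log2_ratio, direction)."""
    de_set.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
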