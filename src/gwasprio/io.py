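"""Readers and writers for the tabular formats the pipeline touches.

Formats
-------
- GWAS summary statistics: tab-delimited with a header; column names are
  configurable via a mapping (defaults: ``snp_id``, ``chrom``, ``pos``,
  ``p_add``).
- Gene catalog: BED4 (chrom, chromStart, chromEnd, name). BED's half-open
  0-based coordinates are converted to the internal 1-based inclusive
  convention at this boundary and nowhere else.
- Gene set: one gene id per line; ``#`` starts a comment.
- Genotype count tables: CSV with a fixed header
  (snp_id, major, minor, case_hom_major, case_het, case_hom_minor,
  control_hom_major, control_het, control_hom_minor).
- SNP association catalog: TSV with snp_id, chrom, pos, trait, p.

Loading never silently drops rows: every rejected row raises with its
(1-based) data-row number, and accepted counts are logged.
"""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import (
    CaseControlTable,
    GeneBestSnp,
    GeneRegion,
    GeneSet,
    GenotypeCounts,
    SnpRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_SUMMARY_COLUMNS: Mapping[str, str] = {
    "snp_id": "snp_id",
    "chrom": "chrom",
    "pos": "pos",
    "p_add": "p_add",
}

GENOTYPE_TABLE_COLUMNS = (
    "snp_id",
    "major",
    "minor",
    "case_hom_major",
    "case_het",
    "case_hom_minor",
    "control_hom_major",
    "control_het",
    "control_hom_minor",
)

CATALOG_COLUMNS = ("snp_id", "chrom", "pos", "trait", "p")


class ConfigurationError(ValueError):
    """A file's header does not match the configured column mapping."""


class ParseError(ValueError):
    """A data row could not be parsed; the message names the row."""


def format_p(p: float | None) -> str:
    """Format a P-value as two-significant-figure scientific notation with an
    upper-case E (e.g. ``1.8E-03``); ``None`` renders as ``n/a``."""
    if p is None:
        return "n/a"
    return f"{p:.1E}"


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write ``text`` to ``path`` atomically (temp file + rename)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _check_duplicates(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SnpRecord]:
    """Read tab-delimited GWAS summary statistics into SnpRecords.

    ``column_map`` maps the internal field names (snp_id, chrom, pos, p_add)
    to the column names used in the file's header.
    """
    colmap = dict(DEFAULT_SUMMARY_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {missing}; header has "
            f"{list(df.columns)}"
        )
    records: list[SnpRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        r = dict(zip(df.columns, row))
        try:
            rec = SnpRecord(
                snp_id=str(r[colmap["snp_id"]]),
                chrom=str(r[colmap["chrom"]]),
                pos=int(r[colmap["pos"]]),
                p_add=float(r[colmap["p_add"]]),
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: row {idx}: {exc}") from exc
        records.append(rec)
    _check_duplicates([r.snp_id for r in records], "snp_id")
    logger.info("read_summary_stats: %s: %d rows accepted, 0 rejected", path, len(records))
    return records


def write_summary_stats(records: Iterable[SnpRecord], path: str | Path) -> None:
    lines = ["snp_id\tchrom\tpos\tp_add"]
    for r in records:
        lines.append(f"{r.snp_id}\t{r.chrom}\t{r.pos}\t{r.p_add!r}")
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Gene catalog (BED4) and gene sets
# ---------------------------------------------------------------------------

def read_gene_regions(path: str | Path) -> list[GeneRegion]:
    """Read a BED4 gene catalog, converting to 1-based inclusive coordinates
    (start = chromStart + 1, end = chromEnd)."""
    regions: list[GeneRegion] = []
    with open(path) as fh:
        for idx, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path}: row {idx}: BED4 requires chrom, chromStart, "
                    f"chromEnd, name; got {len(fields)} field(s)"
                )
            chrom, raw_start, raw_end, name = fields[:4]
            try:
                bed_start, bed_end = int(raw_start), int(raw_end)
            except ValueError as exc:
                raise ParseError(f"{path}: row {idx}: {exc}") from exc
            if bed_start >= bed_end:
                raise ValidationError(
                    f"{path}: row {idx}: empty or inverted interval "
                    f"[{bed_start}, {bed_end})"
                )
            regions.append(
                GeneRegion(gene_id=name, chrom=chrom, start=bed_start + 1, end=bed_end)
            )
    _check_duplicates([g.gene_id for g in regions], "gene_id")
    logger.info("read_gene_regions: %s: %d regions", path, len(regions))
    return regions


def write_gene_regions(regions: Iterable[GeneRegion], path: str | Path) -> None:
    """Write a gene catalog as BED4 (back-converting to half-open 0-based)."""
    lines = [f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}" for g in regions]
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene set: one gene id per line, '#' comments allowed."""
    members: list[str] = []
    with open(path) as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                members.append(token)
    _check_duplicates(members, "gene set member")
    return GeneSet(name=name or Path(path).stem, members=frozenset(members))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    atomic_write_text(path, "\n".join(sorted(gene_set.members)) + "\n")


# ---------------------------------------------------------------------------
# Genotype count tables
# ---------------------------------------------------------------------------

def read_genotype_tables(path: str | Path) -> list[CaseControlTable]:
    """Read a CSV of case/control genotype counts, one SNP per row."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in GENOTYPE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required column(s) {missing}")
    tables: list[CaseControlTable] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        r = dict(zip(df.columns, row))
        try:
            counts = {c: int(r[c]) for c in GENOTYPE_TABLE_COLUMNS[3:]}
            table = CaseControlTable(
                snp_id=str(r["snp_id"]),
                major_allele=str(r["major"]),
                minor_allele=str(r["minor"]),
                cases=GenotypeCounts(
                    counts["case_hom_major"], counts["case_het"], counts["case_hom_minor"]
                ),
                controls=GenotypeCounts(
                    counts["control_hom_major"],
                    counts["control_het"],
                    counts["control_hom_minor"],
                ),
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: row {idx}: {exc}") from exc
        tables.append(table)
    _check_duplicates([t.snp_id for t in tables], "snp_id")
    logger.info("read_genotype_tables: %s: %d tables", path, len(tables))
    return tables


def write_genotype_tables(tables: Iterable[CaseControlTable], path: str | Path) -> None:
    lines = [",".join(GENOTYPE_TABLE_COLUMNS)]
    for t in tables:
        lines.append(
            ",".join(
                [
                    t.snp_id,
                    t.major_allele,
                    t.minor_allele,
                    *map(str, t.cases.as_tuple()),
                    *map(str, t.controls.as_tuple()),
                ]
            )
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SNP association catalog (PheGenI-like TSV)
# ---------------------------------------------------------------------------

def read_snp_catalog(path: str | Path) -> list[SnpRecord]:
    """Read a SNP association catalog (snp_id, chrom, pos, trait, p).

    The trait column is read and ignored; the catalog's role downstream is
    purely positional (window co-localization).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required column(s) {missing}")
    records: list[SnpRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        r = dict(zip(df.columns, row))
        try:
            records.append(
                SnpRecord(
                    snp_id=str(r["snp_id"]),
                    chrom=str(r["chrom"]),
                    pos=int(r["pos"]),
                    p_add=float(r["p"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: row {idx}: {exc}") from exc
    _check_duplicates([r.snp_id for r in records], "snp_id")
    logger.info("read_snp_catalog: %s: %d rows", path, len(records))
    return records


def write_snp_catalog(
    records: Iterable[SnpRecord], path: str | Path, trait: str = "hypertension"
) -> None:
    lines = ["\t".join(CATALOG_COLUMNS)]
    for r in records:
        lines.append(f"{r.snp_id}\t{r.chrom}\t{r.pos}\t{trait}\t{r.p_add!r}")
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Gene report (best SNP per gene)
# ---------------------------------------------------------------------------

def write_gene_report(rows: Iterable[GeneBestSnp], path: str | Path) -> None:
    """Write a per-gene best-SNP report as TSV.

    P-values use the two-significant-figure scientific dialect (``1.8E-03``);
    genes with no SNP coverage render ``n/a`` in the SNP and P fields.
    """
    lines = ["gene_id\tchrom\tbest_snp\tp_add\tn_snps"]
    for r in rows:
        lines.append(
            "\t".join(
                [
                    r.gene_id,
                    r.chrom,
                    r.best_snp_id if r.best_snp_id is not None else "n/a",
                    format_p(r.best_p),
                    str(r.n_snps),
                ]
            )
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_gene_report(path: str | Path) -> list[GeneBestSnp]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows: list[GeneBestSnp] = []
    for r in df.itertuples(index=False):
        uncovered = r.best_snp == "n/a"
        rows.append(
            GeneBestSnp(
                gene_id=r.gene_id,
                chrom=r.chrom,
                best_snp_id=None if uncovered else r.best_snp,
                best_p=None if uncovered else float(r.p_add),
                n_snps=int(r.n_snps),
            )
        )
    return rows
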