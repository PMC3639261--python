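"""End-to-end flows: prioritize -> select -> replicate -> coloc -> power.

Each run reads its inputs, computes everything in memory, then writes all
output files atomically (temp + rename) together with a JSON run manifest
(command, config snapshot, input checksums, seeds, version, timestamp). An
error at any stage leaves no partial report behind.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

from . import __version__
from . import io as gio
from .assoc import allelic_or, bonferroni, hwe_test
from .enrichment import coloc_enrichment, threshold_enrichment
from .power import power_scan
from .regions import assign_snps_to_genes, best_snp_per_gene, rank_and_select
from .simulate import simulate_case_control_table, simulate_landscape, simulate_snp_catalog
from .types import CohortConfig, GeneBestSnp, LandscapeConfig, PowerSpec

logger = logging.getLogger(__name__)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: Mapping[str, Any],
    input_paths: Mapping[str, str | Path],
    seeds: Mapping[str, int] | None = None,
) -> Path:
    manifest = {
        "command": command,
        "config": dict(config),
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in input_paths.items()},
        "seeds": dict(seeds or {}),
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = Path(out_dir) / "manifest.json"
    gio.atomic_write_text(path, json.dumps(manifest, indent=2) + "\n")
    return path


def run_prioritize(
    summary_stats: str | Path,
    genes_bed: str | Path,
    gene_set_path: str | Path,
    out_dir: str | Path,
    threshold: float = 0.005,
    top_k: int = 6,
    include_uncovered: bool = True,
    column_map: Mapping[str, str] | None = None,
) -> dict[str, Any]:
    """Gene-body best-SNP report for the candidate set, sub-threshold
    enrichment against the remaining catalog genes, and top-k selection.

    Writes ``gene_report.tsv`` (candidate-set genes, best-P order),
    ``top_candidates.tsv``, ``enrichment.json`` and ``manifest.json`` under
    ``out_dir``; returns the summary as a dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    snps = gio.read_summary_stats(summary_stats, column_map)
    if not snps:
        raise ValueError(f"no SNPs read from {summary_stats}")
    regions = gio.read_gene_regions(genes_bed)
    gene_set = gio.read_gene_set(gene_set_path)
    catalog_ids = {g.gene_id for g in regions}
    unmapped = sorted(gene_set.members - catalog_ids)
    if unmapped:
        logger.warning("gene set members missing from catalog: %s", unmapped)

    assignment = assign_snps_to_genes(snps, regions)
    gene_best = best_snp_per_gene(assignment, snps)
    chrom_of = {g.gene_id: g.chrom for g in regions}
    gene_best = [
        GeneBestSnp(g.gene_id, g.chrom or chrom_of.get(g.gene_id, ""), g.best_snp_id,
                    g.best_p, g.n_snps)
        for g in gene_best
    ]
    in_set = [g for g in gene_best if g.gene_id in gene_set.members]
    out_set = [g for g in gene_best if g.gene_id not in gene_set.members]
    enr = threshold_enrichment(in_set, out_set, threshold, include_uncovered)
    top = rank_and_select(in_set, top_k)

    report_rows = sorted(
        in_set, key=lambda g: (g.best_p if g.covered else 2.0, g.gene_id)
    )
    gio.write_gene_report(report_rows, out_dir / "gene_report.tsv")
    top_lines = ["gene_id\tbest_snp\tp_add"] + [
        f"{g}\t{s}\t{gio.format_p(p)}" for g, s, p in top
    ]
    gio.atomic_write_text(out_dir / "top_candidates.tsv", "\n".join(top_lines) + "\n")
    summary = {
        "n_snps": len(snps),
        "n_genes_catalog": len(regions),
        "n_set": len(in_set),
        "n_set_unmapped": len(unmapped),
        "threshold": threshold,
        "table": asdict(enr.table),
        "fraction_in_set": enr.fraction_in_set,
        "fraction_out_set": enr.fraction_out_set,
        "p_two_sided": enr.p_two_sided,
        "top_candidates": [{"gene_id": g, "best_snp": s, "p_add": p} for g, s, p in top],
    }
    gio.atomic_write_text(out_dir / "enrichment.json", json.dumps(summary, indent=2) + "\n")
    write_manifest(
        out_dir,
        "prioritize",
        {"threshold": threshold, "top_k": top_k, "include_uncovered": include_uncovered},
        {"summary_stats": summary_stats, "genes_bed": genes_bed, "gene_set": gene_set_path},
    )
    logger.info(
        "prioritize: %d SNPs, %d/%d set genes pass P<%g (vs %d/%d background), "
        "Fisher P=%.3g",
        len(snps), enr.table.a, enr.table.a + enr.table.b, threshold,
        enr.table.c, enr.table.c + enr.table.d, enr.p_two_sided,
    )
    return summary


def run_replicate(
    tables_csv: str | Path,
    out_dir: str | Path,
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
    hwe_method: str = "levene_exact",
) -> dict[str, Any]:
    """Association report for a genotype-count table file.

    Per SNP: allelic OR with Wald CI, trend P (formatted), HWE-in-controls P,
    and Bonferroni-adjusted trend P for ``bonferroni_m`` loci (default: the
    number of rows). Rows whose statistics fail (e.g. monomorphic) are marked
    failed; the run continues.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = gio.read_genotype_tables(tables_csv)
    if not tables:
        raise ValueError(f"no genotype tables in {tables_csv}")
    m = bonferroni_m if bonferroni_m is not None else len(tables)
    header = (
        "snp_id\tmajor\tminor\tmaf_cases\tmaf_controls\tor_per_minor_allele\t"
        "ci_low\tci_high\tp_add\tp_bonferroni\thwe_controls_p\tstatus"
    )
    lines = [header]
    results, failures = [], []
    for t in tables:
        try:
            res = allelic_or(t, alpha=alpha)
            hwe = hwe_test(t.controls, method=hwe_method)
            p_bonf = bonferroni(res.p_trend, m)
            lines.append(
                "\t".join(
                    [
                        t.snp_id, t.major_allele, t.minor_allele,
                        f"{res.maf_cases:.4f}", f"{res.maf_controls:.4f}",
                        f"{res.or_per_minor_allele:.3f}",
                        f"{res.ci_low:.3f}", f"{res.ci_high:.3f}",
                        gio.format_p(res.p_trend), gio.format_p(p_bonf),
                        gio.format_p(hwe.p), "ok",
                    ]
                )
            )
            results.append(
                {
                    "snp_id": t.snp_id,
                    "or": res.or_per_minor_allele,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p_trend": res.p_trend,
                    "p_bonferroni": p_bonf,
                    "hwe_controls_p": hwe.p,
                }
            )
        except (ValueError, ZeroDivisionError) as exc:
            logger.warning("replicate: %s failed: %s", t.snp_id, exc)
            lines.append(
                "\t".join([t.snp_id, t.major_allele, t.minor_allele]
                          + ["n/a"] * 8 + ["failed"])
            )
            failures.append({"snp_id": t.snp_id, "error": str(exc)})
    gio.atomic_write_text(out_dir / "association_report.tsv", "\n".join(lines) + "\n")
    write_manifest(
        out_dir, "replicate", {"alpha": alpha, "bonferroni_m": m, "hwe_method": hwe_method},
        {"tables": tables_csv},
    )
    return {"results": results, "failures": failures, "bonferroni_m": m}


def run_coloc(
    catalog_tsv: str | Path,
    genes_bed: str | Path,
    gene_set_path: str | Path,
    out_dir: str | Path,
    flank: int = 100_000,
) -> dict[str, Any]:
    """Co-localization of catalog SNPs with the candidate set at ``flank``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog = gio.read_snp_catalog(catalog_tsv)
    regions = gio.read_gene_regions(genes_bed)
    gene_set = gio.read_gene_set(gene_set_path)
    res = coloc_enrichment(gene_set, regions, catalog, flank)
    summary = asdict(res) | {"n_catalog_snps": len(catalog)}
    gio.atomic_write_text(out_dir / "coloc.json", json.dumps(summary, indent=2) + "\n")
    write_manifest(
        out_dir, "coloc", {"flank": flank},
        {"catalog": catalog_tsv, "genes_bed": genes_bed, "gene_set": gene_set_path},
    )
    return summary


def run_power(
    n_cases: int,
    n_controls: int,
    maf_grid: list[float],
    or_grid: list[float],
    out_dir: str | Path,
    alpha: float = 0.05,
) -> dict[str, Any]:
    """Analytic power over a MAF x OR grid, written as TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = PowerSpec(n_cases=n_cases, n_controls=n_controls, maf=0.25,
                     or_per_allele=1.1, alpha=alpha)
    table = power_scan(base, maf_grid, or_grid)
    gio.atomic_write_text(out_dir / "power.tsv", table.to_csv(sep="\t", index=False))
    write_manifest(out_dir, "power",
                   {"n_cases": n_cases, "n_controls": n_controls, "alpha": alpha,
                    "maf_grid": list(maf_grid), "or_grid": list(or_grid)}, {})
    return {"table": table.to_dict(orient="records")}


def run_simulate(kind: str, config: Mapping[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Generate synthetic inputs (``landscape``, ``cohort`` or ``catalog``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = dict(config)
    if kind == "landscape":
        lc_fields = set(LandscapeConfig.__dataclass_fields__)
        lc = LandscapeConfig(**{k: v for k, v in cfg.items() if k in lc_fields})
        snps, genes, gene_set = simulate_landscape(lc, out_dir=out_dir)
        summary = {"n_snps": len(snps), "n_genes": len(genes), "set_size": len(gene_set)}
    elif kind == "cohort":
        cc_fields = set(CohortConfig.__dataclass_fields__)
        cc = CohortConfig(**{k: v for k, v in cfg.items() if k in cc_fields})
        table = simulate_case_control_table(cc)
        gio.write_genotype_tables([table], out_dir / "genotype_counts.csv")
        summary = {"snp_id": table.snp_id, "n_cases": table.cases.total,
                   "n_controls": table.controls.total}
    elif kind == "catalog":
        regions = gio.read_gene_regions(cfg["genes_bed"])
        gene_set = gio.read_gene_set(cfg["gene_set"])
        records = simulate_snp_catalog(
            regions, gene_set,
            n_hits_near_set=cfg["n_hits_near_set"],
            n_hits_background=cfg["n_hits_background"],
            flank=cfg.get("flank", 100_000),
            seed=cfg["seed"],
        )
        gio.write_snp_catalog(records, out_dir / "snp_catalog.tsv")
        summary = {"n_catalog_snps": len(records)}
    else:
        raise ValueError(f"unknown simulation kind: {kind!r}")
    write_manifest(out_dir, f"simulate {kind}", cfg, {},
                   seeds={"seed": cfg.get("seed", 0)})
    return summary
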