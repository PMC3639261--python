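"""Packaged published tables used as worked examples and regression anchors.

- ``load_ec_gene_report``: the WTCCC hypertension scan's best SNP per gene
  body for the 71 genes predicted to be specifically expressed in the
  microvascular endothelium (best trend P and Affymetrix 500K SNP coverage
  per gene; 9 genes have no array coverage).
- ``load_replication_genotype_counts``: case/control genotype counts for the
  six SNPs taken to independent replication (5205 grade-2 hypertensive cases
  vs 5320 population-based controls).
- ``load_wtccc_genotype_counts``: the same six SNPs' genotype counts in the
  original WTCCC scan (~2000 cases vs ~3000 shared controls).
"""

from __future__ import annotations

from importlib.resources import files

from .io import read_gene_report, read_genotype_tables
from .types import CaseControlTable, GeneBestSnp

_DATA = files("gwasprio") / "data"


def load_ec_gene_report() -> list[GeneBestSnp]:
    return read_gene_report(str(_DATA / "wtccc_ec_gene_report.tsv"))


def load_replication_genotype_counts() -> list[CaseControlTable]:
    return read_genotype_tables(str(_DATA / "replication_genotype_counts.csv"))


def load_wtccc_genotype_counts() -> list[CaseControlTable]:
    return read_genotype_tables(str(_DATA / "wtccc_genotype_counts.csv"))
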