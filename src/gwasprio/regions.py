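"""Assigning SNPs to gene bodies, best-SNP-per-gene ranking, and flanked
windows for co-localization.

Conventions: gene-body containment and window membership are inclusive at
both boundaries, consistent with 1-based inclusive intervals. A SNP that
falls inside two overlapping genes is assigned to both.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np

from .types import GeneBestSnp, GeneRegion, SnpRecord

logger = logging.getLogger(__name__)


def assign_snps_to_genes(
    snps: Sequence[SnpRecord], regions: Sequence[GeneRegion]
) -> dict[str, list[str]]:
    """Map each gene to the SNPs whose position falls in its body.

    Returns ``{gene_id: [snp_id, ...]}`` with one entry per gene (possibly
    empty). Assignment requires the same chromosome and
    ``gene.start <= pos <= gene.end``. SNPs assigned to no gene are simply
    absent from all lists; they remain available to the caller as background.
    """
    by_chrom: dict[str, list[SnpRecord]] = defaultdict(list)
    for s in snps:
        by_chrom[s.chrom].append(s)
    # sort positions per chromosome once; each gene is then a binary search
    pos_sorted: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: r.pos)
        pos_sorted[chrom] = (
            np.array([r.pos for r in recs], dtype=np.int64),
            [r.snp_id for r in recs],
        )
    assignment: dict[str, list[str]] = {}
    for gene in regions:
        hit: list[str] = []
        if gene.chrom in pos_sorted:
            pos, ids = pos_sorted[gene.chrom]
            lo = int(np.searchsorted(pos, gene.start, side="left"))
            hi = int(np.searchsorted(pos, gene.end, side="right"))
            hit = ids[lo:hi]
        assignment[gene.gene_id] = hit
    n_assigned = len({sid for lst in assignment.values() for sid in lst})
    logger.info(
        "assign_snps_to_genes: %d/%d SNPs inside >=1 of %d genes",
        n_assigned,
        len(snps),
        len(regions),
    )
    return assignment


def best_snp_per_gene(
    assignment: Mapping[str, Sequence[str]], snps: Sequence[SnpRecord]
) -> list[GeneBestSnp]:
    """For each gene, the assigned SNP with the smallest p_add.

    Ties are broken by lexicographically smallest snp_id. Genes with no
    assigned SNPs are emitted with absent best fields. Gene chromosome is
    taken from any assigned SNP; for uncovered genes it is unknown here and
    reported as "" (callers holding the catalog can fill it in).
    """
    by_id = {s.snp_id: s for s in snps}
    out: list[GeneBestSnp] = []
    for gene_id, snp_ids in assignment.items():
        if not snp_ids:
            out.append(GeneBestSnp(gene_id, "", None, None, 0))
            continue
        best = min(
            (by_id[sid] for sid in snp_ids), key=lambda s: (s.p_add, s.snp_id)
        )
        out.append(
            GeneBestSnp(gene_id, best.chrom, best.snp_id, best.p_add, len(snp_ids))
        )
    return out


def rank_and_select(
    gene_best: Sequence[GeneBestSnp], k: int
) -> list[tuple[str, str, float]]:
    """Rank genes ascending by best P and return the top-k covered genes.

    Uncovered genes sort last and are never selected. Ranking ties are broken
    by gene_id. If fewer than ``k`` genes are covered, all covered genes are
    returned with a warning.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    covered = [g for g in gene_best if g.covered]
    covered.sort(key=lambda g: (g.best_p, g.gene_id))
    if len(covered) < k:
        warnings.warn(
            f"requested top-{k} but only {len(covered)} genes have SNP "
            "coverage; returning all covered genes",
            stacklevel=2,
        )
    return [(g.gene_id, g.best_snp_id, g.best_p) for g in covered[:k]]


def genes_near_snps(
    snps: Sequence[SnpRecord],
    regions: Sequence[GeneRegion],
    flank: int,
) -> set[str]:
    """Gene ids with some SNP within ``flank`` bp of the gene body.

    A gene is included iff a SNP on the same chromosome has
    ``start - flank <= pos <= end + flank`` (inclusive at both boundaries).
    With ``flank == 0`` this reduces to gene-body membership.
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    widened = [
        GeneRegion(g.gene_id, g.chrom, max(1, g.start - flank), g.end + flank)
        for g in regions
    ]
    assignment = assign_snps_to_genes(snps, widened)
    return {gene_id for gene_id, hits in assignment.items() if hits}
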