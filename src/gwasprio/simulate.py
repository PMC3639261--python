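"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover every file the pipeline consumes:

- ``simulate_case_control_table``: genotype counts for one SNP under an
  additive per-allele odds-ratio model. Controls are drawn multinomially
  from Hardy-Weinberg proportions at the population MAF (the population ~
  control approximation appropriate for a population-based control group);
  case genotype probabilities are proportional to the Hardy-Weinberg
  proportion times OR^(minor-allele count), normalized.

- ``simulate_landscape``: a genome-scale scan at reduced scale — genes
  placed uniformly without overlap per chromosome, SNPs uniform over the
  genome, null P-values i.i.d. Uniform(0, 1), and for a chosen fraction of
  candidate-set genes one SNP's P drawn from Beta(a, 1) with a < 1 (smaller
  a = stronger enrichment signal). A configurable fraction of genes (applied
  separately inside and outside the set) is forced to have no SNP coverage,
  mirroring array designs that leave some gene bodies uncovered.

- ``simulate_snp_catalog``: an association catalog with a chosen number of
  hits placed within a flank of candidate-set genes and the rest in
  gene-free background, for co-localization tests.

All generators are deterministic given their seed and their outputs pass the
corresponding readers' validation.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import io as gio
from .types import (
    CaseControlTable,
    CohortConfig,
    GeneRegion,
    GeneSet,
    GenotypeCounts,
    LandscapeConfig,
    SnpRecord,
)

logger = logging.getLogger(__name__)


def hwe_genotype_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities (hom-major, het, hom-minor)."""
    q = maf
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def case_genotype_probs(maf: float, or_per_allele: float) -> np.ndarray:
    """Case genotype probabilities under the additive odds-ratio model:
    proportional to HWE proportion x OR^(minor-allele count)."""
    w = hwe_genotype_probs(maf) * or_per_allele ** np.arange(3)
    return w / w.sum()


def simulate_case_control_table(cfg: CohortConfig) -> CaseControlTable:
    """Draw one case-control genotype count table under ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    controls = rng.multinomial(cfg.n_controls, hwe_genotype_probs(cfg.maf))
    cases = rng.multinomial(
        cfg.n_cases, case_genotype_probs(cfg.maf, cfg.or_per_allele)
    )
    return CaseControlTable(
        snp_id=cfg.snp_id,
        major_allele=cfg.major_allele,
        minor_allele=cfg.minor_allele,
        cases=GenotypeCounts(*map(int, cases)),
        controls=GenotypeCounts(*map(int, controls)),
    )


def _place_genes(cfg: LandscapeConfig, rng: np.random.Generator) -> list[GeneRegion]:
    """Place genes uniformly without overlap, round-robin across chromosomes."""
    per_chrom = [cfg.n_genes // cfg.n_chrom] * cfg.n_chrom
    for i in range(cfg.n_genes % cfg.n_chrom):
        per_chrom[i] += 1
    lo, hi = cfg.gene_length_range
    genes: list[GeneRegion] = []
    idx = 0
    for c, n_here in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        lengths = rng.integers(lo, hi + 1, size=n_here)
        # 1 bp minimum gap between consecutive genes keeps them disjoint
        slack = cfg.chrom_length - int(lengths.sum()) - (n_here - 1)
        if slack < 0:
            raise ValueError(
                f"genes do not fit on {chrom}: need {lengths.sum() + n_here - 1} bp, "
                f"have {cfg.chrom_length}"
            )
        cuts = np.sort(rng.integers(0, slack + 1, size=n_here))
        starts = cuts + np.concatenate(([0], np.cumsum(lengths[:-1] + 1))) + 1
        for s, ln in zip(starts, lengths):
            genes.append(GeneRegion(f"G{idx:05d}", chrom, int(s), int(s + ln - 1)))
            idx += 1
    return genes


def simulate_landscape(
    cfg: LandscapeConfig, out_dir: str | Path | None = None
) -> tuple[list[SnpRecord], list[GeneRegion], GeneSet]:
    """Simulate a scan (summary stats), gene catalog, and candidate set.

    If ``out_dir`` is given, the three files are also written in the
    pipeline's input formats (``summary_stats.tsv``, ``genes.bed``,
    ``gene_set.txt``).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _place_genes(cfg, rng)

    gene_ids = [g.gene_id for g in genes]
    set_idx = rng.choice(cfg.n_genes, size=cfg.set_size, replace=False)
    in_set = np.zeros(cfg.n_genes, dtype=bool)
    in_set[set_idx] = True

    # forced-uncovered genes, sampled at the same rate inside and outside the
    # set so a report over the set shows the expected count of n/a rows
    uncovered = np.zeros(cfg.n_genes, dtype=bool)
    for mask in (in_set, ~in_set):
        pool = np.flatnonzero(mask)
        n_unc = int(round(cfg.uncovered_gene_fraction * len(pool)))
        if n_unc:
            uncovered[rng.choice(pool, size=n_unc, replace=False)] = True
    covered_set_idx = np.flatnonzero(in_set & ~uncovered)
    n_enriched = int(round(cfg.fraction_set_enriched * len(covered_set_idx)))
    enriched_idx = (
        rng.choice(covered_set_idx, size=n_enriched, replace=False)
        if n_enriched
        else np.array([], dtype=int)
    )

    # SNP positions uniform over the genome, then moved out of forced-
    # uncovered genes and at least one ensured inside each covered gene
    chrom_of = rng.integers(0, cfg.n_chrom, size=cfg.n_snps)
    pos = rng.integers(1, cfg.chrom_length + 1, size=cfg.n_snps)
    genes_by_chrom: dict[int, list[int]] = {}
    for gi, g in enumerate(genes):
        genes_by_chrom.setdefault(int(g.chrom[3:]) - 1, []).append(gi)

    # vectorized membership: per chromosome, searchsorted over gene starts
    starts_by_chrom = {}
    for c, gidx in genes_by_chrom.items():
        arr = sorted(gidx, key=lambda gi: genes[gi].start)
        starts_by_chrom[c] = (
            np.array([genes[gi].start for gi in arr]),
            np.array([genes[gi].end for gi in arr]),
            np.array(arr),
        )

    def locate(c_arr: np.ndarray, p_arr: np.ndarray) -> np.ndarray:
        """Gene index containing each SNP, or -1."""
        out = np.full(len(p_arr), -1, dtype=int)
        for c, (st, en, gi) in starts_by_chrom.items():
            m = c_arr == c
            if not m.any():
                continue
            j = np.searchsorted(st, p_arr[m], side="right") - 1
            ok = (j >= 0) & (p_arr[m] <= en[np.clip(j, 0, None)])
            res = np.where(ok, gi[np.clip(j, 0, None)], -1)
            out[m] = res
        return out

    host = locate(chrom_of, pos)
    # relocate SNPs landing in forced-uncovered genes until they are outside
    bad = np.flatnonzero((host >= 0) & uncovered[np.clip(host, 0, None)])
    guard = 0
    while bad.size:
        pos[bad] = rng.integers(1, cfg.chrom_length + 1, size=bad.size)
        host[bad] = locate(chrom_of[bad], pos[bad])
        bad = bad[(host[bad] >= 0) & uncovered[np.clip(host[bad], 0, None)]]
        guard += 1
        if guard > 1000:
            raise RuntimeError("could not place SNPs outside uncovered genes")

    # guarantee coverage of every non-forced-uncovered gene: move the SNPs
    # with the highest indices into empty genes
    covered_now = set(host[host >= 0].tolist())
    empty = [gi for gi in range(cfg.n_genes) if not uncovered[gi] and gi not in covered_now]
    if len(empty) > cfg.n_snps:
        raise ValueError("not enough SNPs to cover all genes")
    intergenic = np.flatnonzero(host < 0)
    donors = intergenic[-len(empty):] if len(empty) else np.array([], dtype=int)
    if len(empty) > len(donors):
        raise ValueError("not enough intergenic SNPs to cover all genes")
    for snp_i, gi in zip(donors, empty):
        g = genes[gi]
        chrom_of[snp_i] = int(g.chrom[3:]) - 1
        pos[snp_i] = rng.integers(g.start, g.end + 1)
        host[snp_i] = gi

    p_vals = rng.uniform(0.0, 1.0, size=cfg.n_snps)
    # enriched genes: one SNP inside gets a Beta(a, 1) P-value
    for gi in enriched_idx:
        inside = np.flatnonzero(host == gi)
        chosen = int(rng.choice(inside))
        p_vals[chosen] = rng.beta(cfg.enriched_effect, 1.0)
    p_vals = np.clip(p_vals, np.nextafter(0.0, 1.0), 1.0)

    order = np.lexsort((pos, chrom_of))
    snps = [
        SnpRecord(
            snp_id=f"rs{i:07d}",
            chrom=f"chr{chrom_of[j] + 1}",
            pos=int(pos[j]),
            p_add=float(p_vals[j]),
        )
        for i, j in enumerate(order)
    ]
    gene_set = GeneSet(
        name=cfg.set_name, members=frozenset(gene_ids[i] for i in set_idx)
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        gio.write_summary_stats(snps, out_dir / "summary_stats.tsv")
        gio.write_gene_regions(genes, out_dir / "genes.bed")
        gio.write_gene_set(gene_set, out_dir / "gene_set.txt")
    logger.info(
        "simulate_landscape: %d SNPs, %d genes (%d forced uncovered), set of %d "
        "(%d enriched)",
        cfg.n_snps,
        cfg.n_genes,
        int(uncovered.sum()),
        cfg.set_size,
        len(enriched_idx),
    )
    return snps, genes, gene_set


def simulate_snp_catalog(
    regions: list[GeneRegion],
    gene_set: GeneSet,
    n_hits_near_set: int,
    n_hits_background: int,
    flank: int,
    seed: int,
) -> list[SnpRecord]:
    """Simulate an association catalog for co-localization tests.

    ``n_hits_near_set`` SNPs are placed within ``flank`` of randomly chosen
    candidate-set genes; ``n_hits_background`` SNPs are placed farther than
    ``flank`` from every gene. Catalog P-values are drawn log-uniform in
    [1e-12, 1e-5], the usual range of a genome-wide significant catalog.
    """
    rng = np.random.default_rng(seed)
    set_regions = [g for g in regions if g.gene_id in gene_set.members]
    if n_hits_near_set > 0 and not set_regions:
        raise ValueError("no set genes available to place hits near")
    chrom_max: dict[str, int] = {}
    for g in regions:
        chrom_max[g.chrom] = max(chrom_max.get(g.chrom, 0), g.end + 2 * flank + 10_000)
    records: list[SnpRecord] = []
    for i in range(n_hits_near_set):
        g = set_regions[rng.integers(0, len(set_regions))]
        p_lo = max(1, g.start - flank)
        records.append(
            SnpRecord(
                snp_id=f"cat_set{i:05d}",
                chrom=g.chrom,
                pos=int(rng.integers(p_lo, g.end + flank + 1)),
                p_add=float(10 ** rng.uniform(-12, -5)),
            )
        )
    chroms = sorted(chrom_max)
    placed = 0
    guard = 0
    while placed < n_hits_background:
        chrom = chroms[rng.integers(0, len(chroms))]
        p = int(rng.integers(1, chrom_max[chrom] + 1))
        near_gene = any(
            g.chrom == chrom and g.start - flank <= p <= g.end + flank for g in regions
        )
        guard += 1
        if guard > 100 * max(1, n_hits_background):
            raise RuntimeError("could not place background hits outside gene windows")
        if near_gene:
            continue
        records.append(
            SnpRecord(
                snp_id=f"cat_bg{placed:05d}",
                chrom=chrom,
                pos=p,
                p_add=float(10 ** rng.uniform(-12, -5)),
            )
        )
        placed += 1
    return records
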