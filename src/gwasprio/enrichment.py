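"""Fisher's exact machinery and the two set-level tests.

The two-sided Fisher P follows the conventional exact-test definition: the
sum of hypergeometric probabilities, over all tables with the observed
margins, whose point probability does not exceed that of the observed table
(with a small relative tie tolerance). It is computed by direct enumeration
over the feasible range of cell ``a``.

Two set-level applications:

- ``threshold_enrichment``: is the candidate gene set over-represented among
  genes whose best SNP passes a moderate significance cutoff (sub-threshold
  GWAS signal)?
- ``coloc_enrichment``: is the candidate set over-represented among genes
  lying within a fixed flank of any SNP in an association catalog?
"""

from __future__ import annotations

import logging
import warnings
from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import hypergeom

from .regions import genes_near_snps
from .types import (
    ColocResult,
    EnrichmentResult,
    Fisher2x2,
    GeneBestSnp,
    GeneRegion,
    GeneSet,
    SnpRecord,
)

logger = logging.getLogger(__name__)

TIE_RTOL = 1e-7


def fisher_exact_two_sided(table: Fisher2x2) -> float:
    """Exact two-sided Fisher P for a 2x2 table by full enumeration.

    Degenerate margins (an all-zero row or column) carry no information
    about association; P = 1 is returned with a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, c1, n = a + b, a + c, a + b + c + d
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        warnings.warn("degenerate 2x2 margin; P = 1", stacklevel=2)
        return 1.0
    a_min = max(0, c1 - (n - r1))
    a_max = min(r1, c1)
    a_vals = np.arange(a_min, a_max + 1)
    pmf = hypergeom.pmf(a_vals, n, r1, c1)
    p_obs = pmf[a - a_min]
    p = float(pmf[pmf <= p_obs * (1.0 + TIE_RTOL)].sum())
    return min(1.0, p)


def threshold_enrichment(
    gene_best_in: Sequence[GeneBestSnp],
    gene_best_out: Sequence[GeneBestSnp],
    threshold: float,
    include_uncovered: bool = True,
) -> EnrichmentResult:
    """Sub-threshold enrichment: fraction of in-set genes whose best SNP has
    P below ``threshold``, against the out-of-set background, Fisher-tested.

    ``include_uncovered`` keeps genes with no SNP coverage in the
    denominators (they can never pass the cutoff); this is the default.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if not gene_best_in:
        raise ValueError("in-set gene list is empty")

    def split(genes: Sequence[GeneBestSnp]) -> tuple[int, int]:
        passing = sum(1 for g in genes if g.covered and g.best_p < threshold)
        if include_uncovered:
            rest = len(genes) - passing
        else:
            rest = sum(1 for g in genes if g.covered) - passing
        return passing, rest

    a, b = split(gene_best_in)
    c, d = split(gene_best_out)
    table = Fisher2x2(a, b, c, d)
    return EnrichmentResult(
        threshold=threshold,
        table=table,
        fraction_in_set=a / (a + b) if a + b else 0.0,
        fraction_out_set=c / (c + d) if c + d else 0.0,
        p_two_sided=fisher_exact_two_sided(table),
    )


def coloc_enrichment(
    gene_set: GeneSet,
    universe: Sequence[GeneRegion],
    snps: Sequence[SnpRecord],
    flank: int,
) -> ColocResult:
    """Co-localization enrichment: set membership x lying-within-flank of any
    catalog SNP, over the supplied gene universe."""
    if not universe:
        raise ValueError("gene universe is empty")
    universe_ids = {g.gene_id for g in universe}
    members = set(gene_set.members)
    unmapped = members - universe_ids
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} gene set member(s) not in the universe were "
            f"dropped: {sorted(unmapped)[:5]}...",
            stacklevel=2,
        )
        members -= unmapped
    near = genes_near_snps(snps, universe, flank)
    n_set_near = len(near & members)
    a = n_set_near
    b = len(members) - a
    c = len(near) - a
    d = len(universe_ids) - len(members) - c
    table = Fisher2x2(a, b, c, d)
    return ColocResult(
        flank=flank,
        n_genes_near=len(near),
        n_set_near=n_set_near,
        universe_size=len(universe_ids),
        set_size=len(members),
        p_two_sided=fisher_exact_two_sided(table),
    )


class PermutationNull(NamedTuple):
    p_one_sided: float
    p_two_sided: float


def permutation_set_null(
    set_size: int,
    universe_flags: Sequence[bool],
    observed: int,
    n_perm: int,
    seed: int,
) -> PermutationNull:
    """Empirical null for set-overlap counts by random-set draws.

    Draws ``n_perm`` gene sets of ``set_size`` uniformly without replacement
    from a universe whose genes carry a boolean "positive" flag, and compares
    the overlap (number of flagged genes drawn) with ``observed``. Sampling
    the overlap of a uniform draw without replacement is a hypergeometric
    draw, which is used directly.

    Returns the one-sided enrichment P (fraction of draws with overlap >=
    observed) and a two-sided analogue ordered by empirical point
    probability.
    """
    n_universe = len(universe_flags)
    if set_size > n_universe:
        raise ValueError("set_size exceeds universe size")
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    n_flagged = int(np.count_nonzero(universe_flags))
    rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(n_flagged, n_universe - n_flagged, set_size, size=n_perm)
    p_one = float(np.mean(draws >= observed))
    counts = np.bincount(draws, minlength=max(observed + 1, draws.max() + 1))
    freq = counts / n_perm
    f_obs = freq[observed]
    p_two = float(freq[freq <= f_obs * (1.0 + TIE_RTOL)].sum())
    return PermutationNull(p_one, min(1.0, p_two))
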