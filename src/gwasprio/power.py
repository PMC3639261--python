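"""Analytic power for the allelic test in a case-control design.

Model: controls carry the population minor-allele frequency p0; under a
per-allele odds ratio OR the case allele frequency is

    p1 = OR p0 / (1 + p0 (OR - 1)).

The allelic test compares the two allele-frequency estimates over 2n alleles
per group with a normal z-test; power uses the unpooled standard error under
the alternative:

    SE_alt = sqrt(p1 (1 - p1) / (2 n_cases) + p0 (1 - p0) / (2 n_controls))
    power  = Phi(d / SE_alt - z_{1 - alpha/2}) + Phi(-d / SE_alt - z_{1 - alpha/2})

with d = |p1 - p0| (one-sided tests drop the second term and use
z_{1 - alpha}). The second, far-tail term is negligible for any real effect
but makes the two-sided power exactly continuous at the null: power -> alpha
as OR -> 1. This deliberately simple 2N-allele formulation is the one
consistent with quoting "additive model odds ratios".
"""

from __future__ import annotations

from itertools import product
from typing import Sequence

import pandas as pd
from scipy.stats import norm

from .types import PowerSpec


def case_allele_frequency(maf: float, or_per_allele: float) -> float:
    """Case minor-allele frequency implied by a per-allele OR at control
    frequency ``maf``."""
    return or_per_allele * maf / (1.0 + maf * (or_per_allele - 1.0))


def allelic_power(spec: PowerSpec) -> float:
    """Analytic power of the two-group allelic z-test under ``spec``."""
    if spec.or_per_allele == 1.0:
        return spec.alpha  # continuity at the null
    p0 = spec.maf
    p1 = case_allele_frequency(p0, spec.or_per_allele)
    se_alt = (
        p1 * (1.0 - p1) / (2.0 * spec.n_cases)
        + p0 * (1.0 - p0) / (2.0 * spec.n_controls)
    ) ** 0.5
    z_crit = norm.ppf(1.0 - spec.alpha / (2.0 if spec.two_sided else 1.0))
    d = abs(p1 - p0) / se_alt
    power = norm.cdf(d - z_crit)
    if spec.two_sided:
        power += norm.cdf(-d - z_crit)
    return float(power)


def power_scan(
    base: PowerSpec, maf_grid: Sequence[float], or_grid: Sequence[float]
) -> pd.DataFrame:
    """Power over the cross-product of MAF and OR grids.

    Returns a tidy DataFrame with columns ``maf``, ``or_per_allele``,
    ``power``; all other design parameters come from ``base``.
    """
    if not len(maf_grid) or not len(or_grid):
        raise ValueError("grids must be non-empty")
    rows = []
    for maf, orr in product(maf_grid, or_grid):
        spec = PowerSpec(
            n_cases=base.n_cases,
            n_controls=base.n_controls,
            maf=maf,
            or_per_allele=orr,
            alpha=base.alpha,
            two_sided=base.two_sided,
        )
        rows.append({"maf": maf, "or_per_allele": orr, "power": allelic_power(spec)})
    return pd.DataFrame(rows)
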