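"""Case-control association statistics from genotype count tables.

Implements the crude (covariate-free) additive-model analysis: the allelic
odds ratio with a Wald confidence interval on the log scale, the
Cochran-Armitage trend test (the score test of per-allele logistic
regression without covariates), Hardy-Weinberg testing (asymptotic chi-square
and the exact conditional test on the heterozygote count), Bonferroni
adjustment, and the conventional blood-pressure correction for subjects on
antihypertensive treatment (+15/+10 mmHg systolic/diastolic).
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2, norm

from .types import AssocResult, CaseControlTable, GenotypeCounts, HweResult

logger = logging.getLogger(__name__)

TIE_RTOL = 1e-7


def trend_test(
    cc: CaseControlTable, scores: Sequence[float] = (0.0, 1.0, 2.0)
) -> tuple[float, float]:
    """Cochran-Armitage trend test across genotype classes.

    With case counts r_i, column totals n_i, R cases, S controls, N = R + S
    and scores t_i::

        U      = sum t_i r_i - (R/N) sum t_i n_i
        Var(U) = (R S / N^2) (sum t_i^2 n_i - (sum t_i n_i)^2 / N)
        z      = U / sqrt(Var(U))

    Returns ``(z, p_two_sided)`` from the standard normal (z^2 is chi^2 with
    1 df). A monomorphic table has Var(U) = 0 and returns P = 1 with a
    warning.
    """
    r = np.asarray(cc.cases.as_tuple(), dtype=float)
    s = np.asarray(cc.controls.as_tuple(), dtype=float)
    t = np.asarray(scores, dtype=float)
    n = r + s
    R, S = r.sum(), s.sum()
    N = R + S
    U = float((t * r).sum() - (R / N) * (t * n).sum())
    var_u = (R * S / N**2) * float((t * t * n).sum() - (t * n).sum() ** 2 / N)
    if var_u <= 0.0:
        warnings.warn(f"{cc.snp_id}: monomorphic table, trend test undefined; P = 1",
                      stacklevel=2)
        return 0.0, 1.0
    z = U / np.sqrt(var_u)
    return float(z), float(2.0 * norm.sf(abs(z)))


def allelic_or(cc: CaseControlTable, alpha: float = 0.05) -> AssocResult:
    """Per-minor-allele odds ratio with a Wald CI, plus trend statistics.

    The 2x2 allele table counts 2N alleles per group (minor = n_het +
    2 n_hom_minor). The CI is Wald on log OR with SE = sqrt(sum of inverse
    cells). If any allele cell is zero, the Haldane-Anscombe +0.5 correction
    is applied to all four cells and flagged in the result. A minor or major
    allele absent from *both* groups leaves the OR undefined and raises.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    ca_min = cc.cases.n_minor_alleles
    ca_maj = cc.cases.n_major_alleles
    co_min = cc.controls.n_minor_alleles
    co_maj = cc.controls.n_major_alleles
    if ca_min + co_min == 0 or ca_maj + co_maj == 0:
        raise ValueError(f"{cc.snp_id}: monomorphic allele table, OR undefined")
    cells = np.array([ca_min, ca_maj, co_min, co_maj], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells  # case-minor, case-major, control-minor, control-major
    log_or = np.log(a * d / (b * c))
    se = np.sqrt((1.0 / cells).sum())
    z_crit = norm.ppf(1.0 - alpha / 2.0)
    z, p = trend_test(cc)
    return AssocResult(
        snp_id=cc.snp_id,
        or_per_minor_allele=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z_crit * se)),
        ci_high=float(np.exp(log_or + z_crit * se)),
        p_trend=p,
        z_trend=z,
        maf_cases=ca_min / (2.0 * cc.cases.total),
        maf_controls=co_min / (2.0 * cc.controls.total),
        alpha=alpha,
        continuity_corrected=corrected,
    )


def _hwe_log_pmf(het_vals: np.ndarray, n: int, n_minor: int) -> np.ndarray:
    """Log of the exact conditional probability of each heterozygote count
    given sample size and minor-allele count (Levene's distribution)."""
    hom_minor = (n_minor - het_vals) // 2
    hom_major = n - het_vals - hom_minor
    n_major = 2 * n - n_minor
    log_pmf = (
        gammaln(n + 1)
        - gammaln(hom_major + 1)
        - gammaln(het_vals + 1)
        - gammaln(hom_minor + 1)
        + het_vals * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )
    return log_pmf


def hwe_test(g: GenotypeCounts, method: str = "levene_exact") -> HweResult:
    """Test deviation from Hardy-Weinberg proportions.

    ``chi2_asymptotic``: 1-df chi-square of observed genotype counts against
    n (p^2, 2pq, q^2) at the sample allele frequency.

    ``levene_exact``: the exact conditional distribution of the heterozygote
    count given the allele counts; two-sided P sums the conditional
    probabilities not exceeding that of the observed count.
    """
    if method not in ("chi2_asymptotic", "levene_exact"):
        raise ValueError(f"unknown HWE method: {method!r}")
    n = g.total
    if n == 0:
        raise ValueError("empty genotype table")
    n_minor = g.n_minor_alleles
    n_major = g.n_major_alleles
    q = n_minor / (2.0 * n)
    expected_het = 2.0 * q * (1.0 - q) * n
    if n_minor == 0 or n_major == 0:
        warnings.warn("monomorphic sample, HWE test undefined; P = 1", stacklevel=2)
        return HweResult(method=method, statistic=0.0 if method == "chi2_asymptotic" else None,
                         p=1.0, expected_het=expected_het)
    if method == "chi2_asymptotic":
        expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        observed = np.asarray(g.as_tuple(), dtype=float)
        stat = float(((observed - expected) ** 2 / expected).sum())
        return HweResult(
            method=method,
            statistic=stat,
            p=float(chi2.sf(stat, df=1)),
            expected_het=expected_het,
        )
    # exact: heterozygote counts share the parity of the minor-allele count
    h_min = n_minor % 2
    h_max = min(n_minor, n_major)
    het_vals = np.arange(h_min, h_max + 1, 2)
    log_pmf = _hwe_log_pmf(het_vals, n, n_minor)
    pmf = np.exp(log_pmf - log_pmf.max())
    pmf /= pmf.sum()
    p_obs = pmf[(het_vals == g.n_het).nonzero()[0][0]]
    p = float(pmf[pmf <= p_obs * (1.0 + TIE_RTOL)].sum())
    return HweResult(
        method=method, statistic=None, p=min(1.0, p), expected_het=expected_het
    )


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjust a P-value for m tests: min(1, m p)."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    return min(1.0, m * p)


def adjust_bp_for_treatment(
    sbp: float, dbp: float, treated: bool
) -> tuple[float, float]:
    """Correct observed blood pressure for antihypertensive treatment.

    Treated subjects' observed pressures understate their underlying values;
    the conventional fixed offsets are +15 mmHg systolic and +10 mmHg
    diastolic. Pure function: the caller is responsible for applying it at
    most once per subject.
    """
    if sbp <= 0 or dbp <= 0:
        raise ValueError("blood pressures must be positive")
    if treated:
        return sbp + 15.0, dbp + 10.0
    return sbp, dbp
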