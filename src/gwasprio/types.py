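"""Core domain types for the prioritization/replication pipeline.

All genomic coordinates are 1-based and inclusive at both ends; conversion
from BED's half-open 0-based convention happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ValidationError(ValueError):
    """Raised when a record violates a domain invariant."""


@dataclass(frozen=True, slots=True)
class SnpRecord:
    """One SNP with genomic position and an additive-model association P.

    ``p_add`` is the trend (additive-model) P-value from the source scan.
    """

    snp_id: str
    chrom: str
    pos: int
    p_add: float

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValidationError("snp_id must be non-empty")
        if self.pos < 1:
            raise ValidationError(f"{self.snp_id}: pos must be >= 1, got {self.pos}")
        if not (0.0 < self.p_add <= 1.0):
            raise ValidationError(
                f"{self.snp_id}: p_add must be in (0, 1], got {self.p_add}"
            )


@dataclass(frozen=True, slots=True)
class GeneRegion:
    """A gene body: first-exon start to last-exon end, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if self.start < 1:
            raise ValidationError(f"{self.gene_id}: start must be >= 1")
        if self.start > self.end:
            raise ValidationError(
                f"{self.gene_id}: start ({self.start}) > end ({self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneSet:
    """A named candidate gene set (e.g. genes specifically expressed in the
    microvascular endothelium)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True, slots=True)
class GenotypeCounts:
    """Genotype counts for one group, ordered hom-major / het / hom-minor."""

    n_hom_major: int
    n_het: int
    n_hom_minor: int

    def __post_init__(self) -> None:
        for name in ("n_hom_major", "n_het", "n_hom_minor"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.n_hom_major + self.n_het + self.n_hom_minor

    @property
    def n_minor_alleles(self) -> int:
        return self.n_het + 2 * self.n_hom_minor

    @property
    def n_major_alleles(self) -> int:
        return 2 * self.n_hom_major + self.n_het

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_hom_major, self.n_het, self.n_hom_minor)


@dataclass(frozen=True, slots=True)
class CaseControlTable:
    """Case and control genotype counts for one SNP, with allele labels."""

    snp_id: str
    major_allele: str
    minor_allele: str
    cases: GenotypeCounts
    controls: GenotypeCounts

    def __post_init__(self) -> None:
        if self.major_allele == self.minor_allele:
            raise ValidationError(
                f"{self.snp_id}: major and minor allele labels are identical"
            )
        if self.cases.total == 0:
            raise ValidationError(f"{self.snp_id}: case group is empty")
        if self.controls.total == 0:
            raise ValidationError(f"{self.snp_id}: control group is empty")


@dataclass(frozen=True, slots=True)
class GeneBestSnp:
    """Per-gene summary: the assigned SNP with the smallest p_add.

    ``best_snp_id`` and ``best_p`` are None iff no SNP falls in the gene body
    (``n_snps == 0``).
    """

    gene_id: str
    chrom: str
    best_snp_id: str | None
    best_p: float | None
    n_snps: int

    def __post_init__(self) -> None:
        covered = self.n_snps > 0
        if covered != (self.best_snp_id is not None) or covered != (
            self.best_p is not None
        ):
            raise ValidationError(
                f"{self.gene_id}: best fields must be present iff n_snps > 0"
            )

    @property
    def covered(self) -> bool:
        return self.n_snps > 0


@dataclass(frozen=True, slots=True)
class Fisher2x2:
    """A 2x2 count table: a = in-set & positive, b = in-set & negative,
    c = out-set & positive, d = out-set & negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("2x2 cells must be >= 0")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("2x2 table is all-zero")


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    """Set-level sub-threshold enrichment of best-SNP P-values."""

    threshold: float
    table: Fisher2x2
    fraction_in_set: float
    fraction_out_set: float
    p_two_sided: float


@dataclass(frozen=True, slots=True)
class ColocResult:
    """Set-membership x near-SNP 2x2 over a gene universe at a fixed flank."""

    flank: int
    n_genes_near: int
    n_set_near: int
    universe_size: int
    set_size: int
    p_two_sided: float


@dataclass(frozen=True, slots=True)
class AssocResult:
    """Per-allele association statistics for one case-control table."""

    snp_id: str
    or_per_minor_allele: float
    ci_low: float
    ci_high: float
    p_trend: float
    z_trend: float
    maf_cases: float
    maf_controls: float
    alpha: float = 0.05
    continuity_corrected: bool = False


@dataclass(frozen=True, slots=True)
class HweResult:
    """Hardy-Weinberg test result (asymptotic chi2 or exact conditional)."""

    method: str
    statistic: float | None
    p: float
    expected_het: float


@dataclass(frozen=True, slots=True)
class PowerSpec:
    """Design parameters for analytic case-control allelic-test power."""

    n_cases: int
    n_controls: int
    maf: float
    or_per_allele: float
    alpha: float = 0.05
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValidationError(f"maf must be in (0, 0.5], got {self.maf}")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.or_per_allele <= 0:
            raise ValidationError("or_per_allele must be > 0")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("sample sizes must be >= 1")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated case-control genotype-count cohort."""

    n_cases: int
    n_controls: int
    maf: float
    or_per_allele: float
    seed: int
    snp_id: str = "snp_sim"
    major_allele: str = "G"
    minor_allele: str = "A"

    def __post_init__(self) -> None:
        if not (0.0 < self.maf < 1.0):
            raise ValidationError(f"maf must be in (0, 1), got {self.maf}")
        if self.or_per_allele <= 0:
            raise ValidationError("or_per_allele must be > 0")


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of a simulated genome-scale scan with a candidate set.

    Defaults emulate the study layout at reduced scale: a dense scan over a
    multi-chromosome genome, a 71-gene candidate set of which a fraction has
    no array coverage, and Beta(a, 1)-distributed P-values at enriched genes.
    """

    seed: int
    n_chrom: int = 4
    chrom_length: int = 25_000_000
    n_genes: int = 800
    gene_length_range: tuple[int, int] = (5_000, 100_000)
    n_snps: int = 20_000
    set_size: int = 71
    fraction_set_enriched: float = 0.0
    enriched_effect: float = 0.05
    uncovered_gene_fraction: float = 0.0
    set_name: str = "candidate_set"

    def __post_init__(self) -> None:
        if self.set_size > self.n_genes:
            raise ValidationError("set_size must be <= n_genes")
        for name in ("fraction_set_enriched", "uncovered_gene_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.gene_length_range
        if not (1 <= lo <= hi):
            raise ValidationError("invalid gene_length_range")
        if not (0.0 < self.enriched_effect):
            raise ValidationError("enriched_effect must be > 0")
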