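"""Simulation configuration and validation."""

from __future__ import annotations

from dataclasses import dataclass, field

from .datatypes import ConfigurationError

__all__ = ["SimulationConfig"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic genotype/phenotype/twin generator.

    The defaults describe the study conditions the package is exercised
    under: a common-SNP panel (MAF >= 0.01) with blockwise LD, a polygenic
    phenotype with total SNP heritability 0.45 concentrated at genic SNPs,
    age/sex/cohort covariate effects, a handful of planted cryptic relatives,
    and MZ/DZ twin samples generated under an ACE decomposition
    (0.60, 0.02, 0.38), i.e. population twin correlations 0.62 / 0.32.

    Attributes
    ----------
    n_subjects, n_snps
        Cohort and panel size.
    block_size
        SNPs per LD block; haplotypes are independent across blocks.
    ld_rho
        Target lag-1 allele correlation of the within-block Markov chain,
        in [0, 1).  Clipped per adjacent pair to the range feasible for the
        two SNPs' allele frequencies.
    maf_range
        (low, high) bounds of the uniform per-SNP allele-frequency draw,
        within (0, 0.5].
    frac_genic
        Fraction of the SNP span covered by synthetic genes.
    causal_fraction_by_category
        Category -> fraction of that category's SNPs that carry effects.
    h2_by_category
        Category -> target proportion of phenotypic variance; must sum to
        ``h2_total``.  An empty map means one "all" category at ``h2_total``.
    h2_total
        Total SNP heritability in [0, 1).
    covariate_effect_sd
        Scale of the age/sex/cohort fixed effects (0 switches them off).
    missing_score_fraction
        Fraction of SNPs left without a conservation score.
    n_mz_pairs, n_dz_pairs, ace_true
        Twin sample design; ``ace_true = (a2, c2, e2)`` sums to 1.
    n_related_pairs, related_kinship
        Planted cryptic-relatedness design.
    seed
        Seed for the single generator all simulators draw from.
    """

    n_subjects: int = 2000
    n_snps: int = 8000
    block_size: int = 20
    ld_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_genic: float = 0.5
    causal_fraction_by_category: dict[str, float] = field(
        default_factory=lambda: {"genic": 0.05, "intergenic": 0.05}
    )
    h2_by_category: dict[str, float] = field(
        default_factory=lambda: {"genic": 0.30, "intergenic": 0.15}
    )
    h2_total: float = 0.45
    covariate_effect_sd: float = 0.3
    n_cohorts: int = 3
    missing_score_fraction: float = 0.02
    n_mz_pairs: int = 134
    n_dz_pairs: int = 99
    ace_true: tuple[float, float, float] = (0.60, 0.02, 0.38)
    n_related_pairs: int = 0
    related_kinship: float = 0.05
    bp_spacing: int = 1000
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects <= 0 or self.n_snps <= 0:
            raise ConfigurationError("n_subjects and n_snps must be positive")
        if self.block_size <= 0:
            raise ConfigurationError("block_size must be positive")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigurationError("ld_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0.0 <= self.frac_genic <= 1.0:
            raise ConfigurationError("frac_genic must lie in [0, 1]")
        if not 0.0 <= self.h2_total < 1.0:
            raise ConfigurationError("h2_total must lie in [0, 1)")
        for cat, h2 in self.h2_by_category.items():
            if not 0.0 <= h2 <= 1.0:
                raise ConfigurationError(f"h2_by_category[{cat!r}] outside [0, 1]")
        if self.h2_by_category and sum(self.h2_by_category.values()) > self.h2_total + 1e-12:
            raise ConfigurationError("sum of h2_by_category exceeds h2_total")
        if abs(sum(self.ace_true) - 1.0) > 1e-12:
            raise ConfigurationError("ace_true components must sum to 1 within 1e-12")
        if any(v < 0 for v in self.ace_true):
            raise ConfigurationError("ace_true components must be nonnegative")
        if self.n_related_pairs < 0 or 2 * self.n_related_pairs > self.n_subjects:
            raise ConfigurationError("n_related_pairs must satisfy 0 <= 2*pairs <= n_subjects")
        if self.n_related_pairs and not 0.0 < self.related_kinship <= 1.0:
            raise ConfigurationError("related_kinship must lie in (0, 1]")
        if not 0.0 <= self.missing_score_fraction < 1.0:
            raise ConfigurationError("missing_score_fraction must lie in [0, 1)")
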