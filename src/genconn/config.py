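"""Configuration objects for the synthetic cohort generator and the pipeline.

The simulation emulates the shape of a pediatric imaging-genetics cohort:
a subjects x SNPs dosage matrix, per-subject symmetric connectome matrices
of mean fascicle fractional anisotropy (fFA), a covariate table
(age, sex, scanner, genetic ancestry factors), behavior variables, and GWAS
summary statistics for polygenic scoring.  A single sparse latent mode of
known canonical correlation ``rho`` links a subset of "risk" SNPs to a
subset of connections, so every downstream stage can be validated against
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study shape the pipeline was designed for:
    678 subjects, 1877 risk SNPs, a 120-region parcellation (hence
    7140 unique connections), and a single planted genome-connectome
    mode.  Tests and the acceptance script run scaled-down versions by
    overriding the counts.

    Parameters
    ----------
    n_subjects, n_snps, n_nodes
        Cohort shape.  ``n_nodes`` must be even and at least 10.
    n_causal_snps
        Number of SNPs loading on the planted genetic latent.
    n_signal_connections
        Number of connections carrying the planted connectomic latent.
    rho
        Planted canonical correlation between the genetic latent ``g``
        and the connectomic latent ``m``; in [0, 1].
    maf_range
        Uniform range for minor-allele frequencies, in (0, 0.5].
    causal_snp_loading
        Strength of the shared latent factor on causal-SNP allele
        probabilities (per unit of the standard-normal factor).  This
        makes causal SNPs inter-correlated so the planted genetic
        direction carries excess variance and survives PCA reduction.
    connection_effect_scale
        Scale of per-edge effects of the connectomic latent on signal
        connections (fFA units).  Effects are drawn with a negative mean
        so the planted mode is predominantly hypoconnective.
    confound_effect_sd
        SD of per-edge linear effects of age / sex / scanner / GAF
        (standardized) on connection strengths; 0 disables confounds.
    noise_sd
        SD of i.i.d. edge-level measurement noise (fFA units).
    mediation_a, mediation_b, mediation_cprime
        Path coefficients for behavior generation: behaviors are
        ``y = cprime * g + b * m + noise``.  ``mediation_a`` is the
        exposure->mediator path used by the standalone mediation-triple
        generator; for pipeline latents the realized g->m path is rho.
    n_behaviors_continuous, n_behaviors_dichotomous, n_signal_behaviors
        Behavior battery shape; the first ``n_signal_behaviors`` carry
        the (b, cprime) paths, the rest are pure noise.
    behavior_noise_sd, behavior_confound_sd, behavior_missing_rate
        Behavior noise SD, SD of age/sex slopes on behaviors, and the
        per-cell missingness rate.
    sumstats_base_n, sumstats_beta
        Effective sample size of the synthetic base GWAS and the true
        per-causal-SNP effect size used for summary statistics.
    sumstats_noise_scale
        Multiplier on the per-SNP estimation-noise SD (1 = the SE
        implied by ``sumstats_base_n``; 0 = noise-free betas).
    ld_block_size, ld_block_r2
        Optional block-exchangeable LD: SNPs in consecutive blocks of
        ``ld_block_size`` share pairwise r2 ``ld_block_r2``.  Disabled
        (independent SNPs) when ``ld_block_size`` is None.
    n_latent_modes
        Number of planted modes; the default single mode reflects the
        one strongly significant mode this analysis targets.
    seed
        Master seed; every sub-generator derives its own stream from it.
    """

    n_subjects: int = 678
    n_snps: int = 1877
    n_nodes: int = 120
    n_causal_snps: int = 100
    n_signal_connections: int = 200
    rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_snp_loading: float = 0.15
    connection_effect_scale: float = 0.03
    confound_effect_sd: float = 0.02
    noise_sd: float = 0.05
    mediation_a: float = 0.6
    mediation_b: float = 0.3
    mediation_cprime: float = 0.2
    n_behaviors_continuous: int = 8
    n_behaviors_dichotomous: int = 4
    n_signal_behaviors: int = 6
    behavior_noise_sd: float = 1.0
    behavior_confound_sd: float = 0.2
    behavior_missing_rate: float = 0.0
    n_scanners: int = 3
    n_gafs: int = 2
    sumstats_base_n: int = 50_000
    sumstats_beta: float = 0.05
    sumstats_noise_scale: float = 1.0
    ld_block_size: Optional[int] = None
    ld_block_r2: float = 0.0
    n_latent_modes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_snps < 1:
            raise ValueError("n_subjects and n_snps must be positive")
        if self.n_nodes < 10 or self.n_nodes % 2 != 0:
            raise ValueError("n_nodes must be even and >= 10")
        if not 0 <= self.n_causal_snps <= self.n_snps:
            raise ValueError("n_causal_snps must be in [0, n_snps]")
        n_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if not 0 <= self.n_signal_connections <= n_edges:
            raise ValueError(
                f"n_signal_connections must be in [0, {n_edges}] for "
                f"{self.n_nodes} nodes"
            )
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        lo, hi = self.maf_range
        # a degenerate point range (lo == hi) is a valid fixed-MAF setting;
        # a zero MAF is not
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.confound_effect_sd < 0:
            raise ValueError("confound_effect_sd must be nonnegative")
        if not 0.0 <= self.behavior_missing_rate < 1.0:
            raise ValueError("behavior_missing_rate must be in [0, 1)")
        if self.ld_block_size is not None and self.ld_block_size < 2:
            raise ValueError("ld_block_size must be >= 2 when set")
        if not 0.0 <= self.ld_block_r2 < 1.0:
            raise ValueError("ld_block_r2 must be in [0, 1)")
        if self.n_latent_modes < 1:
            raise ValueError("n_latent_modes must be >= 1")

    @property
    def n_connections(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunConfig:
    """End-to-end pipeline settings (thresholds mirror the analysis defaults).

    ``mode_permutations`` calibrates mode significance (10,000 by default),
    ``behavior_permutations`` drives the combined probability test (1000),
    and ``prs_permutations`` corrects the PRS threshold scan (10,000).
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_components: int = 100
    standardize: bool = False
    mode_permutations: int = 10_000
    behavior_permutations: int = 1_000
    prs_permutations: int = 10_000
    gwas_p_threshold: float = 5e-8
    proxy_r2_threshold: float = 0.8
    fdr_threshold: float = 0.05
    prs_upper_bound: float = 1.0
    clump_r2: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mode_permutations", "behavior_permutations",
                     "prs_permutations", "n_components"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.gwas_p_threshold < 1:
            raise ValueError("gwas_p_threshold must be in (0, 1)")
        if not 0 < self.proxy_r2_threshold < 1:
            raise ValueError("proxy_r2_threshold must be in (0, 1)")
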