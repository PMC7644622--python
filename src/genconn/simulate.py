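"""Synthetic imaging-genetics cohort with a planted genome-connectome mode.

The generator emits every input the pipeline consumes — dosages, symmetric
fFA connectomes, covariates, behaviors and GWAS summary statistics — with
known ground truth.  A sparse genetic latent ``g`` (a standardized weighted
sum of causal-SNP dosages) and a connectomic latent ``m`` with
``corr(g, m) = rho`` link a subset of risk SNPs to a subset of connections;
behaviors are partially mediated by ``m``.

Causal SNPs are drawn conditional on a shared standard-normal factor
(allele probability ``maf_j + loading_j * f_i``) so the planted genetic
direction carries excess variance: without this, PCA reduction of
independent SNPs would discard the latent and no downstream method could
recover it.  ``g`` is still defined from the realized dosages, so its
stated definition holds exactly.

Reproducibility: one master seed; each sub-generator uses the stream
``default_rng(SeedSequence((seed, STREAM_ID)))`` with fixed per-component
stream ids, so components are independently reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats, special

from .config import SimulationConfig
from .datatypes import (BehaviorTable, ConnectomeSet, GenotypeTable,
                        GroundTruth, SummaryStats)

_STREAMS = {"genotypes": 0, "joint_mode": 1, "behaviors": 2,
            "sumstats": 3, "mediation_triple": 4}

_PSYCH_PHENOTYPES = [
    "schizophrenia", "bipolar disorder", "major depressive disorder",
    "alcohol use disorder", "autism spectrum disorder", "ADHD",
    "cross-disorder", "anxiety",
]
_OTHER_PHENOTYPES = [
    ("migraine", "neurological"), ("epilepsy", "neurological"),
    ("educational attainment", "behavior-cognition"),
    ("cognitive performance", "behavior-cognition"),
    ("subcortical volume", "brain-morphology-function"),
    ("white matter hyperintensity", "brain-morphology-function"),
    ("asthma", "control"), ("type 2 diabetes", "control"),
]
_ALLELES = np.array(list("ACGT"))


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((config.seed, _STREAMS[stream])))


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def simulate_genotypes(config: SimulationConfig) -> GenotypeTable:
    """Draw the subjects x SNPs dosage matrix and per-SNP metadata.

    Non-causal SNPs are independent Binomial(2, MAF) with
    MAF ~ Uniform(maf_range).  Causal SNPs share a latent factor (see
    module docstring).  Every SNP is annotated with a phenotype label and
    a synthetic genome-wide-significant catalog p-value (< 5e-8).  When
    ``ld_block_size`` is set, non-causal SNPs within consecutive blocks
    share a per-block latent giving pairwise r2 ~ ld_block_r2.
    """
    rng = _rng(config, "genotypes")
    n, p = config.n_subjects, config.n_snps
    lo, hi = config.maf_range

    mafs = rng.uniform(lo, hi, size=p)
    causal_idx = rng.choice(p, size=config.n_causal_snps, replace=False)
    causal_idx.sort()
    # keep causal MAFs away from the boundary so factor loadings do not
    # saturate the [0.01, 0.99] allele-probability clip
    mafs[causal_idx] = rng.uniform(max(lo, 0.2), hi, size=len(causal_idx))

    factor = rng.standard_normal(n)
    signs = rng.choice([-1.0, 1.0], size=len(causal_idx))
    loadings = config.causal_snp_loading * signs

    dosages = np.empty((n, p), dtype=float)
    is_causal = np.zeros(p, dtype=bool)
    is_causal[causal_idx] = True

    noncausal_idx = np.flatnonzero(~is_causal)
    if config.ld_block_size is None or config.ld_block_r2 == 0.0:
        dosages[:, noncausal_idx] = rng.binomial(
            2, mafs[noncausal_idx], size=(n, len(noncausal_idx)))
        block_of = None
    else:
        # block-exchangeable LD: SNPs in a block share the block MAF and
        # each allele is copied from a block-shared draw with probability
        # c = r2^(1/4) (else drawn privately), giving pairwise allele
        # correlation c^2 and dosage r2 = c^4 = ld_block_r2
        k = config.ld_block_size
        copy_p = config.ld_block_r2 ** 0.25
        block_of = np.full(p, -1, dtype=int)
        for b_start in range(0, len(noncausal_idx), k):
            block = noncausal_idx[b_start:b_start + k]
            block_of[block] = b_start // k
            maf_b = mafs[block[0]]
            mafs[block] = maf_b
            shared = rng.binomial(1, maf_b, size=(n, 2))
            for j in block:
                private = rng.binomial(1, maf_b, size=(n, 2))
                use_shared = rng.random((n, 2)) < copy_p
                dosages[:, j] = np.where(use_shared, shared,
                                         private).sum(axis=1)

    for pos, j in enumerate(causal_idx):
        prob = np.clip(mafs[j] + loadings[pos] * factor, 0.01, 0.99)
        dosages[:, j] = rng.binomial(2, prob)

    snp_ids = [f"rs{100000 + i}" for i in range(p)]
    groups, labels = [], []
    for j in range(p):
        if is_causal[j]:
            labels.append(_PSYCH_PHENOTYPES[j % len(_PSYCH_PHENOTYPES)])
            groups.append("psychiatric")
        else:
            lab, grp = _OTHER_PHENOTYPES[j % len(_OTHER_PHENOTYPES)]
            labels.append(lab)
            groups.append(grp)
    meta = pd.DataFrame({
        "effect_allele": rng.choice(_ALLELES, size=p),
        "phenotype": labels,
        "phenotype_group": groups,
        "gwas_p": 10.0 ** rng.uniform(-30.0, np.log10(5e-8), size=p),
        "maf": mafs,
    }, index=pd.Index(snp_ids, name="snp_id"))

    subjects = pd.Index([f"sub{i:05d}" for i in range(n)], name="subject_id")
    planted = {
        "causal_snp_ids": [snp_ids[j] for j in causal_idx],
        "causal_loadings": loadings,
        "factor": factor,
        "ld_block_of": block_of,
    }
    return GenotypeTable(
        dosages=pd.DataFrame(dosages, index=subjects, columns=snp_ids),
        snp_meta=meta, planted=planted)


def simulate_joint_mode(
    config: SimulationConfig, genotypes: GenotypeTable,
) -> tuple[ConnectomeSet, pd.DataFrame, GroundTruth]:
    """Plant the genome-connectome mode and build connectomes + covariates.

    ``g`` = standardized weighted sum of causal-SNP dosages (weights equal
    the factor loadings used at genotype generation).  ``m`` mixes ``g``
    with orthogonalized fresh noise so that corr(g, m) = rho exactly.
    Signal connections get ``baseline + effect_j * m_i``; all connections
    get linear age/sex/scanner/GAF effects (scale ``confound_effect_sd``)
    and i.i.d. Gaussian noise.  Baselines are Uniform(0.2, 0.8), above the
    tractography stopping floor of fFA 0.2.
    """
    if genotypes.planted is None:
        raise ValueError("genotypes must come from simulate_genotypes")
    if config.rho == 1.0 and config.noise_sd > 0:
        raise ValueError(
            "rho=1 is unattainable with noise_sd > 0 on the latent chain")
    rng = _rng(config, "joint_mode")
    n = config.n_subjects
    n_edges = config.n_connections

    causal_ids = genotypes.planted["causal_snp_ids"]
    weights = np.asarray(genotypes.planted["causal_loadings"], float)
    weights = weights / np.linalg.norm(weights)
    Xc = genotypes.dosages[causal_ids].to_numpy(float)
    g = _standardize((Xc - Xc.mean(axis=0)) @ weights)

    eps = rng.standard_normal(n)
    eps = _standardize(eps - g * (eps @ g) / (g @ g))  # exactly orthogonal
    m = config.rho * g + np.sqrt(1.0 - config.rho ** 2) * eps
    if config.rho < 1.0:
        m = _standardize(m)

    signal_edges = rng.choice(n_edges, size=config.n_signal_connections,
                              replace=False)
    signal_edges.sort()
    effects = config.connection_effect_scale * rng.normal(
        -1.0, 0.5, size=len(signal_edges))

    # covariates: age in years, binary sex, categorical scanner, GAFs
    age = np.clip(rng.normal(12.8, 4.9, size=n), 3.0, 21.0)
    sex = rng.integers(0, 2, size=n).astype(float)
    scanner = rng.integers(0, config.n_scanners, size=n)
    gafs = rng.standard_normal((n, config.n_gafs))
    subjects = genotypes.subject_ids
    cov = pd.DataFrame({"age": age, "sex": sex,
                        "scanner": [f"site{s}" for s in scanner]},
                       index=subjects)
    for k in range(config.n_gafs):
        cov[f"gaf{k + 1}"] = gafs[:, k]

    baseline = rng.uniform(0.2, 0.8, size=n_edges)
    edges = np.tile(baseline, (n, 1))
    edges[:, signal_edges] += np.outer(m, effects)
    if config.confound_effect_sd > 0:
        design = np.column_stack([
            _standardize(age), sex - sex.mean(),
            *( (scanner == s).astype(float) - np.mean(scanner == s)
               for s in range(1, config.n_scanners) ),
            gafs,
        ])
        betas = rng.normal(0.0, config.confound_effect_sd,
                           size=(design.shape[1], n_edges))
        edges += design @ betas
    edges += rng.normal(0.0, config.noise_sd, size=edges.shape)

    iu = np.triu_indices(config.n_nodes, k=1)
    mats = np.zeros((n, config.n_nodes, config.n_nodes))
    mats[:, iu[0], iu[1]] = edges
    mats[:, iu[1], iu[0]] = edges

    truth = GroundTruth(
        causal_snp_ids=list(causal_ids),
        signal_connection_ids=signal_edges,
        true_genetic_weights=weights,
        true_connection_effects=effects,
        latent_g=g, latent_m=m, rho=config.rho)
    connectomes = ConnectomeSet(
        subject_ids=list(subjects),
        node_labels=[f"region{i + 1:03d}" for i in range(config.n_nodes)],
        matrices=mats)
    return connectomes, cov, truth


def simulate_behaviors(
    config: SimulationConfig, truth: GroundTruth,
    covariates: pd.DataFrame | None = None,
    subject_ids=None,
) -> BehaviorTable:
    """Behavior battery partially mediated by the connectomic latent.

    Signal variables follow ``lin = cprime * g + b * m`` (continuous:
    ``y = lin + noise``; dichotomous: Bernoulli(logistic(lin))); the rest
    are pure noise.  Small age/sex slopes (scale ``behavior_confound_sd``)
    are added when covariates are supplied, exercising the adjustment
    step.  Higher values always mean higher vulnerability.  Per-variable
    (a, b, cprime) triples are recorded in ``truth.behavior_paths`` with
    a = rho (the realized g -> m path for standardized latents).
    """
    rng = _rng(config, "behaviors")
    g, m = truth.latent_g, truth.latent_m
    n = len(g)
    if subject_ids is None:
        subject_ids = (covariates.index if covariates is not None
                       else pd.RangeIndex(n))
    conf = np.zeros(n)
    if covariates is not None and config.behavior_confound_sd > 0:
        age_z = _standardize(covariates["age"].to_numpy(float))
        sex_c = covariates["sex"].to_numpy(float)
        sex_c = sex_c - sex_c.mean()
    else:
        age_z = sex_c = None

    n_total = config.n_behaviors_continuous + config.n_behaviors_dichotomous
    values, types = {}, {}
    for v in range(n_total):
        is_signal = v < config.n_signal_behaviors
        b = config.mediation_b if is_signal else 0.0
        cp = config.mediation_cprime if is_signal else 0.0
        lin = cp * g + b * m
        if age_z is not None:
            lin = lin + (rng.normal(0, config.behavior_confound_sd) * age_z
                         + rng.normal(0, config.behavior_confound_sd) * sex_c)
        if v < config.n_behaviors_continuous:
            name = f"beh_cont{v + 1:02d}"
            y = lin + rng.normal(0, config.behavior_noise_sd, size=n)
            types[name] = "continuous"
        else:
            name = f"beh_dich{v + 1:02d}"
            y = rng.binomial(1, special.expit(lin)).astype(float)
            types[name] = "dichotomous"
        if config.behavior_missing_rate > 0:
            mask = rng.random(n) < config.behavior_missing_rate
            y = np.where(mask, np.nan, y)
        values[name] = y
        truth.behavior_paths[name] = (truth.rho, b, cp)

    df = pd.DataFrame(values, index=subject_ids)
    return BehaviorTable(values=df, types=pd.Series(types),
                         vulnerability_sign=pd.Series(1, index=df.columns))


def simulate_sumstats(
    config: SimulationConfig, truth: GroundTruth, genotypes: GenotypeTable,
) -> SummaryStats:
    """Base-GWAS summary statistics for polygenic scoring.

    True betas are ``sumstats_beta * weight_sign`` on causal SNPs and 0
    elsewhere; estimates add Gaussian noise at the SE implied by the base
    sample size (SE = 1/sqrt(2 MAF (1-MAF) n_base)), and p-values are the
    two-sided normal tail of beta/SE.  Non-causal SNPs therefore have
    Uniform(0, 1) p-values and causal SNPs are enriched at small p.
    """
    rng = _rng(config, "sumstats")
    meta = genotypes.snp_meta
    mafs = meta["maf"].to_numpy(float)
    se = config.sumstats_noise_scale / np.sqrt(
        2.0 * mafs * (1.0 - mafs) * config.sumstats_base_n)
    beta_true = np.zeros(len(meta))
    causal_pos = meta.index.get_indexer(truth.causal_snp_ids)
    signs = np.sign(truth.true_genetic_weights)
    beta_true[causal_pos] = config.sumstats_beta * signs
    if config.sumstats_noise_scale == 0:
        beta_hat = beta_true
        se_eff = 1.0 / np.sqrt(2.0 * mafs * (1.0 - mafs)
                               * config.sumstats_base_n)
        pvals = 2.0 * stats.norm.sf(np.abs(beta_hat) / se_eff)
    else:
        beta_hat = beta_true + rng.normal(0.0, se)
        pvals = 2.0 * stats.norm.sf(np.abs(beta_hat) / se)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame({
        "snp_id": meta.index,
        "effect_allele": meta["effect_allele"].to_numpy(),
        "beta": beta_hat,
        "p": pvals,
    }).reset_index(drop=True)
    return SummaryStats(table=table, phenotype="synthetic-psychiatric")


def simulate_mediation_triple(
    a: float, b: float, cprime: float, n: int, seed: int = 0,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standalone (x, m, y) triple with known paths, for mediation checks.

    x ~ N(0,1); m = a x + e_m; y = cprime x + b m + e_y, with independent
    Gaussian noise of SD ``noise_sd`` on each equation.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence((seed, _STREAMS["mediation_triple"])))
    x = rng.standard_normal(n)
    m = a * x + noise_sd * rng.standard_normal(n)
    y = cprime * x + b * m + noise_sd * rng.standard_normal(n)
    return x, m, y


def simulate_cohort(config: SimulationConfig):
    """Convenience wrapper: genotypes, connectomes, covariates, behaviors,
    summary stats and ground truth in one call."""
    genotypes = simulate_genotypes(config)
    connectomes, covariates, truth = simulate_joint_mode(config, genotypes)
    behaviors = simulate_behaviors(config, truth, covariates=covariates)
    sumstats = simulate_sumstats(config, truth, genotypes)
    return genotypes, connectomes, covariates, behaviors, sumstats, truth
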