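"""End-to-end orchestration: the core CCA pipeline shared by the primary
analysis and every robustness rerun, plus `run_all` which executes all
stages on a synthetic cohort and writes the artifacts of a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .cca import (canonical_strengths, fit_cca, orient_mode, reduce_pca,
                  variance_explained)
from .config import RunConfig
from .datatypes import CCAMode, GenotypeTable, PermutationNull
from .mediation import combined_behavior_test, combined_mediation_test
from .permutation import (bh_fdr, build_strength_table, null_variance_ratio,
                          permutation_test_modes, strength_pvalues)
from .prep import (adjust_behaviors, adjust_confounds, filter_behaviors,
                   vectorize)
from .prs import build_threshold_grid, clump, permutation_correct, prs_scan
from .select import select_snps
from .simulate import simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class CCAPipelineResult:
    """Everything downstream stages need from one adjust -> PCA -> CCA ->
    strengths pass."""

    mode: CCAMode                  # mode 1, sign-oriented
    modes: list
    gen_strengths: np.ndarray
    conn_strengths: np.ndarray
    gen_block: np.ndarray          # genetic features entering PCA
    conn_block: np.ndarray         # adjusted connection features
    gen_scores_pca: np.ndarray
    conn_scores_pca: np.ndarray
    subject_index: pd.Index


def run_cca_pipeline(dosages: pd.DataFrame, conn_vec: pd.DataFrame,
                     covariates: pd.DataFrame, n_components: int = 100,
                     standardize: bool = False,
                     adjust_genetic: bool = False) -> CCAPipelineResult:
    """The shared analysis core: adjust connections for confounds
    (optionally the genotypes too), reduce both blocks by PCA, fit CCA,
    orient mode 1 (mean connection strength <= 0) and compute canonical
    strengths.  Robustness scenarios call this on transformed inputs so
    every rerun uses the identical code path."""
    if not dosages.index.equals(conn_vec.index):
        raise ValueError("genotype and connectome subjects differ")
    conn_adj = adjust_confounds(conn_vec, covariates)
    gen_block = dosages.to_numpy(float)
    if adjust_genetic:
        gen_block = adjust_confounds(gen_block, covariates)
    k = min(n_components, dosages.shape[0] - 1, dosages.shape[1],
            conn_vec.shape[1])
    pca_g = reduce_pca(gen_block, n_components=k, standardize=standardize)
    pca_c = reduce_pca(conn_adj.to_numpy(float), n_components=k,
                       standardize=standardize)
    modes = fit_cca(pca_g.scores, pca_c.scores)
    mode1 = modes[0]
    conn_strengths = canonical_strengths(conn_adj.to_numpy(float),
                                         mode1.y_scores)
    mode1 = orient_mode(mode1, conn_strengths)
    if mode1.flipped:
        conn_strengths = -conn_strengths
        modes = [modes[0].flip()] + modes[1:]
        mode1 = modes[0]
    gen_strengths = canonical_strengths(gen_block, mode1.x_scores)
    return CCAPipelineResult(
        mode=mode1, modes=modes,
        gen_strengths=gen_strengths, conn_strengths=conn_strengths,
        gen_block=gen_block, conn_block=conn_adj.to_numpy(float),
        gen_scores_pca=pca_g.scores, conn_scores_pca=pca_c.scores,
        subject_index=dosages.index)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {"simulation": config.simulation.to_dict(),
         **{k: v for k, v in vars(config).items() if k != "simulation"}},
        sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(config: RunConfig, out_dir) -> dict:
    """Execute all stages on a synthetic cohort and write the run
    directory: simulate -> select-snps -> prep -> cca -> permtest -> prs
    -> behavior -> robustness.  Returns the provenance manifest (also
    written as manifest.json).  Deterministic stages are bit-identical
    across reruns with the same config."""
    from .robustness import mean_connectivity_correlation, split_half

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)
    stages = []

    # 1. simulate
    sim = config.simulation
    genotypes, connectomes, covariates, behaviors, sumstats, truth = \
        simulate_cohort(sim)
    gio.write_cohort(out / "inputs", genotypes, connectomes, covariates,
                     behaviors, sumstats, truth)
    stages.append("simulate")

    # 2. select-snps (the synthetic metadata acts as the catalog; all
    # SNPs are genotyped, so every catalog row is a direct hit)
    catalog = genotypes.snp_meta.reset_index()[
        ["snp_id", "phenotype", "phenotype_group", "gwas_p"]]
    selected = select_snps(catalog, genotypes.snp_ids,
                           p_threshold=config.gwas_p_threshold,
                           r2_threshold=config.proxy_r2_threshold)
    gio.write_table(selected, out / "selected_snps.tsv")
    dosages = genotypes.dosages[selected["snp_id"].unique()]
    stages.append("select-snps")

    # 3. prep
    conn_vec, edge_idx = vectorize(connectomes)
    behaviors_kept = filter_behaviors(behaviors)
    behaviors_adj = adjust_behaviors(behaviors_kept, covariates)
    gio.write_table(edge_idx, out / "edge_index.tsv", index=False)
    stages.append("prep")

    # 4. cca
    seeds = _stage_seeds(config.seed)
    result = run_cca_pipeline(dosages, conn_vec, covariates,
                              n_components=config.n_components,
                              standardize=config.standardize)
    ve_conn, _ = variance_explained(result.conn_block, result.mode.y_scores)
    ve_gen, _ = variance_explained(result.gen_block, result.mode.x_scores)
    scores = pd.DataFrame({
        "genetic_score": result.mode.x_scores,
        "connectomic_score": result.mode.y_scores,
    }, index=result.subject_index)
    gio.write_table(scores, out / "canonical_scores.tsv")
    stages.append("cca")

    # 5. permtest
    mode_p, null = permutation_test_modes(
        result.gen_scores_pca, result.conn_scores_pca,
        B=config.mode_permutations, seed=seeds["permtest"],
        X_x=result.gen_block, X_y=result.conn_block,
        strengths_x=result.gen_strengths,
        strengths_y=result.conn_strengths)
    p_gen = strength_pvalues(result.gen_strengths, null, block="x")
    p_conn = strength_pvalues(result.conn_strengths, null, block="y")
    snp_groups = genotypes.snp_meta.loc[dosages.columns, "phenotype"]
    q_gen = bh_fdr(p_gen, snp_groups.to_numpy())
    q_conn = bh_fdr(p_conn)
    gen_table = build_strength_table(dosages.columns, result.gen_strengths,
                                     p_gen, q_gen, snp_groups)
    conn_table = build_strength_table(conn_vec.columns,
                                      result.conn_strengths, p_conn, q_conn,
                                      ["connections"] * conn_vec.shape[1])
    gio.write_table(gen_table, out / "genetic_strengths.tsv", index=False)
    gio.write_table(conn_table, out / "connection_strengths.tsv",
                    index=False)
    ratio_conn = null_variance_ratio(ve_conn, null, block="y")
    ratio_gen = null_variance_ratio(ve_gen, null, block="x")
    mode_summary = {
        "r": [float(m.r) for m in result.modes[:10]],
        "p": mode_p[:10].tolist(),
        "varexp_conn": ve_conn, "varexp_gen": ve_gen,
        "varexp_ratio_conn": ratio_conn.ratio,
        "varexp_ratio_gen": ratio_gen.ratio,
    }
    gio.write_json(mode_summary, out / "mode_summary.json")
    stages.append("permtest")

    # 6. prs
    gaf_cols = [c for c in covariates.columns if c.startswith("gaf")]
    gafs = covariates[gaf_cols]
    clumped = clump(sumstats, ld=None, r2=config.clump_r2)
    grid = build_threshold_grid(config.prs_upper_bound)
    scan = prs_scan(result.mode.y_scores, genotypes, clumped, gafs, grid)
    corrected_p, best_thr, best_p = permutation_correct(
        result.mode.y_scores, genotypes, clumped, gafs, grid,
        B=config.prs_permutations, seed=seeds["prs"])
    best_row = scan.loc[scan["p"].idxmin()]
    prs_summary = {"best_threshold": best_thr,
                   "delta_r2": float(best_row["delta_r2"]),
                   "p_uncorrected": best_p,
                   "p_corrected": corrected_p}
    gio.write_table(scan, out / "prs_scan.tsv", index=False)
    gio.write_json(prs_summary, out / "prs_summary.json")
    stages.append("prs")

    # 7. behavior (+ mediation)
    beh = combined_behavior_test(result.mode.y_scores, behaviors_adj,
                                 B=config.behavior_permutations,
                                 seed=seeds["behavior"])
    med = combined_mediation_test(result.mode.x_scores,
                                  result.mode.y_scores, behaviors_adj,
                                  B=config.behavior_permutations,
                                  seed=seeds["mediation"])
    gio.write_table(beh.per_variable, out / "behavior_correlations.tsv",
                    index=False)
    gio.write_table(med.per_variable, out / "mediation.tsv", index=False)
    gio.write_json({"behavior_combined_p": beh.p, "behavior_T": beh.T,
                    "mediation_combined_p": med.p, "mediation_T": med.T},
                   out / "behavior_summary.json")
    stages.append("behavior")

    # 8. robustness (split-half + mean-connectivity summary by default)
    halves = split_half(dosages, conn_vec, covariates,
                        n_components=config.n_components,
                        seed=seeds["robustness"],
                        reference=result)
    mc_r, mc_p = mean_connectivity_correlation(
        conn_vec.to_numpy(float), result.mode.y_scores,
        seed=seeds["robustness"])
    rob = {"split_half": [vars(h) for h in halves],
           "mean_connectivity": {"r": mc_r, "p": mc_p}}
    gio.write_json(rob, out / "robustness.json")
    stages.append("robustness")

    manifest = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": stages,
        "n_subjects": sim.n_subjects,
        "n_snps_selected": int(dosages.shape[1]),
        "n_connections": int(conn_vec.shape[1]),
        "mode_r": float(result.mode.r),
        "mode_p": float(mode_p[0]),
    }
    gio.write_json(manifest, out / "manifest.json")
    return manifest


def _stage_seeds(master: int) -> dict:
    """Named per-stage seeds derived from the master seed (kept < 2^31)."""
    names = ["permtest", "prs", "behavior", "mediation", "robustness"]
    ss = np.random.SeedSequence(master)
    states = ss.generate_state(len(names))
    return {name: int(s % (2 ** 31)) for name, s in zip(names, states)}
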