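"""Clumping + thresholding polygenic risk scores and their association
with the connectomic canonical score.

Scores are weighted effect-allele dosage sums over SNPs passing each
inclusion p-threshold of a high-resolution grid (5e-8 to 1.0 in steps of
5e-5, truncated at the base study's optimal threshold).  The association
with the target is Delta R^2 = R^2(target ~ PRS + GAFs) - R^2(target ~
GAFs); scanning many thresholds inflates the best association, so the
final two-tailed p-value is calibrated by permuting the target and
repeating the whole scan.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeTable, SummaryStats

logger = logging.getLogger(__name__)

GRID_START = 5e-8
GRID_STEP = 5e-5


def build_threshold_grid(upper_bound: float) -> np.ndarray:
    """Inclusion p-threshold grid: {5e-8, 5e-8 + 5e-5, ...} truncated at
    ``upper_bound`` (appended if not on the grid).  An upper bound below
    5e-8 yields the single-point grid {upper_bound}."""
    if not 0 < upper_bound <= 1:
        raise ValueError("upper_bound must lie in (0, 1]")
    if upper_bound < GRID_START:
        return np.array([upper_bound])
    n_steps = int(np.floor((upper_bound - GRID_START) / GRID_STEP))
    grid = GRID_START + GRID_STEP * np.arange(n_steps + 1)
    grid = grid[grid <= upper_bound]
    if not np.isclose(grid[-1], upper_bound, rtol=0, atol=1e-15):
        grid = np.append(grid, upper_bound)
    return grid


def clump(sumstats: SummaryStats, ld: pd.DataFrame | None = None,
          r2: float = 0.1) -> SummaryStats:
    """Greedy LD clumping: visit SNPs by ascending p; drop a SNP whose r2
    with an already-kept SNP exceeds ``r2``.  ``ld`` is a pairwise table
    (index_snp_id, proxy_snp_id, r_squared); with no table the input is
    returned unchanged (independent SNPs need no clumping)."""
    table = sumstats.table
    if ld is None or len(ld) == 0:
        return sumstats
    pair_r2: dict[tuple[str, str], float] = {}
    for rec in ld.itertuples(index=False):
        key = (rec.index_snp_id, rec.proxy_snp_id)
        pair_r2[key] = max(pair_r2.get(key, 0.0), float(rec.r_squared))
        rkey = key[::-1]
        pair_r2[rkey] = max(pair_r2.get(rkey, 0.0), float(rec.r_squared))
    kept: list[str] = []
    for rec in table.sort_values(["p", "snp_id"]).itertuples():
        drop = any(pair_r2.get((rec.snp_id, k), 0.0) > r2 for k in kept)
        if not drop:
            kept.append(rec.snp_id)
    mask = table["snp_id"].isin(kept)
    logger.info("clumping kept %d of %d SNPs", int(mask.sum()), len(table))
    return SummaryStats(table=table[mask].reset_index(drop=True),
                        phenotype=sumstats.phenotype)


def _aligned_dosages(genotypes: GenotypeTable, sumstats: SummaryStats):
    """Match summary-stat SNPs to genotyped SNPs with identical effect
    allele; mismatches are dropped with a logged count.  Missing dosages
    are imputed as 2 * sample MAF (the column mean)."""
    table = sumstats.table.set_index("snp_id")
    shared = table.index.intersection(genotypes.snp_ids)
    geno_alleles = genotypes.snp_meta.loc[shared, "effect_allele"]
    match = table.loc[shared, "effect_allele"].to_numpy() \
        == geno_alleles.to_numpy()
    if (~match).any():
        logger.info("dropping %d SNPs with effect-allele mismatch",
                    int((~match).sum()))
    snps = shared[match]
    D = genotypes.dosages[snps].to_numpy(float)
    if np.isnan(D).any():
        col_mean = np.nanmean(D, axis=0)  # = 2 * sample MAF
        nan_r, nan_c = np.where(np.isnan(D))
        D[nan_r, nan_c] = col_mean[nan_c]
    return D, table.loc[snps, "beta"].to_numpy(float), \
        table.loc[snps, "p"].to_numpy(float), snps


def score_prs(genotypes: GenotypeTable, sumstats: SummaryStats,
              threshold: float) -> pd.Series:
    """Per-subject PRS at one threshold: sum over SNPs with p <= threshold
    of beta * dosage (effect-allele counts).  All-zero with a warning when
    no SNP passes."""
    D, beta, p, _ = _aligned_dosages(genotypes, sumstats)
    include = p <= threshold
    if not include.any():
        logger.warning("no SNP passes threshold %.3g; scores are zero",
                       threshold)
        return pd.Series(0.0, index=genotypes.subject_ids, name="prs")
    scores = D[:, include] @ beta[include]
    return pd.Series(scores, index=genotypes.subject_ids, name="prs")


def delta_r2(target, prs, gafs: pd.DataFrame | None = None
             ) -> tuple[float, float]:
    """Variance in the target explained by the PRS beyond GAF covariates.

    Returns (Delta R^2, two-tailed p) where Delta R^2 = R^2(full) -
    R^2(GAFs only) and p is the t-test on the PRS coefficient of the full
    model."""
    y = np.asarray(target, float)
    s = np.asarray(prs, float)
    n = len(y)
    G = (np.empty((n, 0)) if gafs is None or gafs.shape[1] == 0
         else np.asarray(gafs, float))
    ones = np.ones((n, 1))
    X_null = np.hstack([ones, G])
    X_full = np.hstack([ones, G, s[:, None]])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("PRS is collinear with the GAF covariates")

    def _r2(X):
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        tss = np.sum((y - y.mean()) ** 2)
        return 1.0 - resid @ resid / tss, beta, resid

    r2_null, _, _ = _r2(X_null)
    r2_full, beta, resid = _r2(X_full)
    df = n - X_full.shape[1]
    sigma2 = resid @ resid / df
    XtX_inv = np.linalg.inv(X_full.T @ X_full)
    se = np.sqrt(sigma2 * XtX_inv[-1, -1])
    t = beta[-1] / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(r2_full - r2_null), float(p)


def _residualize(M: np.ndarray, Q: np.ndarray | None) -> np.ndarray:
    if Q is None:
        return M - M.mean(axis=0)
    Mc = M - M.mean(axis=0)
    return Mc - Q @ (Q.T @ Mc)


def _threshold_score_matrix(genotypes, sumstats, grid):
    """Scores at every grid threshold, deduplicated to distinct SNP sets
    (thresholds between two consecutive SNP p-values give identical
    scores)."""
    D, beta, p, _ = _aligned_dosages(genotypes, sumstats)
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    # cumulative weighted dosage sums along ascending p
    cum = np.cumsum(D[:, order] * beta[order], axis=1)
    counts = np.searchsorted(p_sorted, np.asarray(grid), side="right")
    uniq_counts = np.unique(counts[counts > 0])
    S = cum[:, uniq_counts - 1]
    return S, counts, uniq_counts


def prs_scan(target, genotypes: GenotypeTable, sumstats: SummaryStats,
             gafs: pd.DataFrame | None, grid) -> pd.DataFrame:
    """Delta R^2 and model p at every threshold of the grid."""
    rows = []
    for thr in np.asarray(grid, float):
        s = score_prs(genotypes, sumstats, thr)
        if s.std() == 0:
            rows.append((thr, np.nan, np.nan))
            continue
        d, p = delta_r2(target, s, gafs)
        rows.append((thr, d, p))
    return pd.DataFrame(rows, columns=["threshold", "delta_r2", "p"])


def permutation_correct(target, genotypes: GenotypeTable,
                        sumstats: SummaryStats,
                        gafs: pd.DataFrame | None, grid,
                        B: int = 10_000, seed: int | None = 0
                        ) -> tuple[float, float, float]:
    """Permutation correction for the threshold scan.

    The observed statistic is the best (largest) |partial correlation|
    between target and PRS given GAFs over all grid thresholds — the
    monotone equivalent of the smallest model p.  For each permutation
    the target rows are shuffled and the scan repeated; the corrected
    two-tailed p is (1 + #{best_b >= best_obs}) / (B + 1).

    Returns (corrected p, best threshold, observed best model p).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(target, float)
    n = len(y)
    if gafs is not None and gafs.shape[1] > 0:
        G = np.asarray(gafs, float)
        Gc = np.hstack([np.ones((n, 1)), G])
        Q, _ = np.linalg.qr(Gc)
        k_gaf = G.shape[1]
    else:
        Q, k_gaf = None, 0

    S, counts, uniq_counts = _threshold_score_matrix(genotypes, sumstats,
                                                     grid)
    Sr = _residualize(S, Q)
    norms = np.linalg.norm(Sr, axis=0)
    ok = norms > 0
    Sr = Sr[:, ok] / norms[ok]
    if Sr.shape[1] == 0:
        raise ValueError("no threshold yields a non-constant PRS")

    yr = _residualize(y[:, None], Q)[:, 0]
    yr = yr / np.linalg.norm(yr)
    obs_abs_r = np.abs(Sr.T @ yr)
    best_idx = int(np.argmax(obs_abs_r))
    df = n - k_gaf - 2
    t_obs = obs_abs_r[best_idx] * np.sqrt(
        df / max(1e-300, 1.0 - obs_abs_r[best_idx] ** 2))
    best_p_obs = 2.0 * stats.t.sf(t_obs, df)
    # map back to the smallest grid threshold attaining that SNP set
    best_count = uniq_counts[ok][best_idx]
    grid = np.asarray(grid, float)
    best_threshold = float(grid[np.flatnonzero(counts == best_count)[0]])

    rng = np.random.default_rng(seed)
    best_obs = obs_abs_r[best_idx]
    exceed = 0
    chunk = max(1, min(256, B))
    done = 0
    while done < B:
        nb = min(chunk, B - done)
        Yp = np.stack([y[rng.permutation(n)] for _ in range(nb)], axis=1)
        Yr = _residualize(Yp, Q)
        Yr = Yr / np.linalg.norm(Yr, axis=0)
        best_b = np.max(np.abs(Sr.T @ Yr), axis=0)
        exceed += int((best_b >= best_obs - 1e-15).sum())
        done += nb
    corrected = (1 + exceed) / (B + 1)
    return float(corrected), best_threshold, float(best_p_obs)
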