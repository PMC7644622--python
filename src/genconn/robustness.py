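"""Robustness battery: split-half reproducibility, PC-count sensitivity,
SNP-subset and subject-exclusion reruns, plus network summaries (hubs and
the mean-connectivity correlation).

Every scenario is an input transformation followed by the identical
pipeline core (:func:`genconn.pipeline.run_cca_pipeline`); reproduced
canonical strengths are compared with the originals after sign
alignment, since the CCA sign is arbitrary (the reproduced mode is
flipped to maximize the correlation with the original and the aligned
value is reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pipeline import CCAPipelineResult, run_cca_pipeline

logger = logging.getLogger(__name__)


@dataclass
class ReproducibilityReport:
    scenario: str
    gen_strength_r: float | None
    conn_strength_r: float | None
    n_subjects: int
    flipped: bool


def _aligned_corr(original: np.ndarray, reproduced: np.ndarray
                  ) -> tuple[float, bool]:
    mask = np.isfinite(original) & np.isfinite(reproduced)
    r = float(np.corrcoef(original[mask], reproduced[mask])[0, 1])
    return (abs(r), r < 0)


def _compare(reference: CCAPipelineResult, rerun: CCAPipelineResult,
             scenario: str, compare_gen: bool = True
             ) -> ReproducibilityReport:
    conn_r, flipped = _aligned_corr(reference.conn_strengths,
                                    rerun.conn_strengths)
    gen_r = None
    if compare_gen:
        g, _ = _aligned_corr(reference.gen_strengths, rerun.gen_strengths)
        gen_r = g
    return ReproducibilityReport(scenario=scenario, gen_strength_r=gen_r,
                                 conn_strength_r=conn_r,
                                 n_subjects=len(rerun.subject_index),
                                 flipped=flipped)


def split_half(dosages: pd.DataFrame, conn_vec: pd.DataFrame,
               covariates: pd.DataFrame, n_components: int = 100,
               seed: int | None = 0,
               reference: CCAPipelineResult | None = None
               ) -> list[ReproducibilityReport]:
    """Rerun the full pipeline in two mutually exclusive random halves of
    the population and correlate each half's canonical strengths with the
    full-sample ones."""
    n = len(dosages)
    if n < 40:
        raise ValueError("split-half needs at least 40 subjects")
    if reference is None:
        reference = run_cca_pipeline(dosages, conn_vec, covariates,
                                     n_components=n_components)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    halves = [np.sort(perm[: n // 2]), np.sort(perm[n // 2:])]
    reports = []
    for i, idx in enumerate(halves, start=1):
        k = min(n_components, len(idx) - 1)
        rerun = run_cca_pipeline(dosages.iloc[idx], conn_vec.iloc[idx],
                                 covariates.iloc[idx], n_components=k)
        reports.append(_compare(reference, rerun, f"split-half-{i}"))
    return reports


def pc_sensitivity(dosages: pd.DataFrame, conn_vec: pd.DataFrame,
                   covariates: pd.DataFrame,
                   k_list=(50, 75, 100, 125, 150), baseline: int = 100
                   ) -> list[ReproducibilityReport]:
    """Rerun with different PC counts and correlate canonical strengths
    against the baseline-K solution.  Invalid K values are skipped with a
    warning."""
    reference = run_cca_pipeline(dosages, conn_vec, covariates,
                                 n_components=baseline)
    k_max = min(len(dosages) - 1, dosages.shape[1], conn_vec.shape[1])
    reports = []
    for k in k_list:
        if not 1 <= k <= k_max:
            logger.warning("skipping invalid PC count %d", k)
            continue
        rerun = run_cca_pipeline(dosages, conn_vec, covariates,
                                 n_components=k)
        reports.append(_compare(reference, rerun, f"pcs-{k}"))
    return reports


def snp_subset_rerun(dosages: pd.DataFrame, conn_vec: pd.DataFrame,
                     covariates: pd.DataFrame, snp_phenotypes: pd.Series,
                     phenotype_subset, n_components: int = 100,
                     B: int = 999, seed: int | None = 0
                     ) -> tuple[ReproducibilityReport, float]:
    """Rerun with SNPs restricted to a phenotype subset; the reproduced
    connection-strength vector is correlated with the original, with a
    permutation p obtained by shuffling the edge labels."""
    subset = set(phenotype_subset)
    keep = [s for s in dosages.columns
            if snp_phenotypes.get(s) in subset]
    if len(keep) < 2:
        raise ValueError("phenotype subset selects fewer than 2 SNPs")
    reference = run_cca_pipeline(dosages, conn_vec, covariates,
                                 n_components=n_components)
    k = min(n_components, len(keep))
    rerun = run_cca_pipeline(dosages[keep], conn_vec, covariates,
                             n_components=k)
    report = _compare(reference, rerun, "snp-subset", compare_gen=False)
    rng = np.random.default_rng(seed)
    a, b = reference.conn_strengths, rerun.conn_strengths
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    obs = abs(np.corrcoef(a, b)[0, 1])
    exceed = sum(
        abs(np.corrcoef(a, b[rng.permutation(len(b))])[0, 1]) >= obs
        for _ in range(B))
    return report, (1 + exceed) / (B + 1)


def exclude_subjects_rerun(dosages: pd.DataFrame, conn_vec: pd.DataFrame,
                           covariates: pd.DataFrame, exclusion_flags,
                           n_components: int = 100
                           ) -> ReproducibilityReport:
    """Rerun without flagged subjects (e.g. those exhibiting behaviors
    related to psychiatric vulnerability)."""
    flags = np.asarray(exclusion_flags, bool)
    keep = ~flags
    if keep.sum() < 30:
        raise ValueError("fewer than 30 subjects remain after exclusion")
    reference = run_cca_pipeline(dosages, conn_vec, covariates,
                                 n_components=n_components)
    k = min(n_components, int(keep.sum()) - 1)
    rerun = run_cca_pipeline(dosages.loc[keep], conn_vec.loc[keep],
                             covariates.loc[keep], n_components=k)
    return _compare(reference, rerun, "exclude-subjects")


def mean_connectivity_correlation(conn_vectors, conn_score,
                                  B: int = 9999, seed: int | None = 0
                                  ) -> tuple[float, float]:
    """Correlation between the per-subject mean connection strength and
    the connectomic canonical score, with a two-sided permutation p from
    shuffling the scores."""
    X = np.asarray(conn_vectors, float)
    s = np.asarray(conn_score, float)
    means = X.mean(axis=1)
    r = float(np.corrcoef(means, s)[0, 1])
    rng = np.random.default_rng(seed)
    mz = (means - means.mean()) / (means.std() * np.sqrt(len(s)))
    sz = (s - s.mean()) / (s.std() * np.sqrt(len(s)))
    perm_r = np.array([
        mz @ sz[rng.permutation(len(s))] for _ in range(B)])
    p = (1 + (np.abs(perm_r) >= abs(r) - 1e-15).sum()) / (B + 1)
    return r, float(p)


def compute_hubs(strength_table: pd.DataFrame, edge_index: pd.DataFrame,
                 n_nodes: int, q_threshold: float = 0.05,
                 average: bool = False) -> pd.DataFrame:
    """Per-node hub summary: the sum (or mean, with ``average=True``) of
    canonical connection strengths over incident connections with
    q < q_threshold.  Nodes classify as 'hypo' (< 0), 'hyper' (> 0) or
    'none' (no significant incident connection, or an exact zero sum)."""
    sig = strength_table["q"].to_numpy() < q_threshold
    strengths = strength_table["strength"].to_numpy()
    node_sum = np.zeros(n_nodes)
    node_count = np.zeros(n_nodes, dtype=int)
    ni = edge_index["node_i"].to_numpy()
    nj = edge_index["node_j"].to_numpy()
    for e in np.flatnonzero(sig):
        node_sum[ni[e]] += strengths[e]
        node_sum[nj[e]] += strengths[e]
        node_count[ni[e]] += 1
        node_count[nj[e]] += 1
    value = node_sum.copy()
    if average:
        with np.errstate(invalid="ignore"):
            value = np.where(node_count > 0, node_sum / node_count, 0.0)
    cls = np.where(node_count == 0, "none",
                   np.where(value < 0, "hypo",
                            np.where(value > 0, "hyper", "none")))
    return pd.DataFrame({"node": np.arange(n_nodes),
                         "summed_strength": node_sum,
                         "n_significant": node_count,
                         "value": value, "class": cls})
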