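"""Connectome vectorization, confound adjustment and behavior preparation.

Connection strengths are adjusted for age, sex, scanner site and genetic
ancestry factors (GAFs) by per-feature linear regression,

    C = C0 + b_age age + b_sex sex + b_scanner scanner + b_GAF GAF,

and the residuals feed the CCA.  Behaviors are filtered (more than ten
observations; dichotomous variables need a minority level of at least 5%)
and adjusted for age and sex — linear regression for continuous variables,
logistic regression (response residuals y - p_hat) for dichotomous ones.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .datatypes import BehaviorTable, ConnectomeSet

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-10


def edge_index(n_nodes: int) -> pd.DataFrame:
    """Canonical row-major upper-triangle edge index.

    Internal node indices are 0-based; file output uses 1-based labels.
    """
    i, j = np.triu_indices(n_nodes, k=1)
    return pd.DataFrame({"edge_id": np.arange(len(i)),
                         "node_i": i, "node_j": j})


def vectorize(connectomes: ConnectomeSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten symmetric matrices to a subjects x n(n-1)/2 edge matrix.

    Edges follow row-major upper-triangle order: (0,1), (0,2), ...,
    (0,n-1), (1,2), ...  Returns (edge matrix, edge index).  Asymmetry
    beyond 1e-10 or non-finite entries raise with the worst offender named.
    """
    mats = connectomes.matrices
    if not np.isfinite(mats).all():
        s, i, j = np.unravel_index(
            np.argmax(~np.isfinite(mats)), mats.shape)
        raise ValueError(
            f"non-finite connectome entry: subject "
            f"{connectomes.subject_ids[s]!r} at ({i}, {j})")
    asym = np.abs(mats - mats.transpose(0, 2, 1))
    worst = asym.max()
    if worst > SYMMETRY_TOL:
        s, i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"asymmetric connectome: subject {connectomes.subject_ids[s]!r} "
            f"entry ({i}, {j}) differs by {worst:.3e} (tol {SYMMETRY_TOL})")
    iu = np.triu_indices(connectomes.n_nodes, k=1)
    values = mats[:, iu[0], iu[1]]
    idx = edge_index(connectomes.n_nodes)
    cols = [f"e{i}_{j}" for i, j in zip(idx["node_i"], idx["node_j"])]
    df = pd.DataFrame(values,
                      index=pd.Index(connectomes.subject_ids,
                                     name="subject_id"),
                      columns=cols)
    return df, idx


def devectorize(edges: pd.DataFrame | np.ndarray, n_nodes: int,
                subject_ids=None, node_labels=None) -> ConnectomeSet:
    """Inverse of :func:`vectorize`; restores symmetric zero-diagonal
    matrices exactly."""
    values = np.asarray(edges, float)
    expected = n_nodes * (n_nodes - 1) // 2
    if values.shape[1] != expected:
        raise ValueError(f"expected {expected} edges for {n_nodes} nodes, "
                         f"got {values.shape[1]}")
    if subject_ids is None:
        subject_ids = (list(edges.index) if isinstance(edges, pd.DataFrame)
                       else list(range(values.shape[0])))
    if node_labels is None:
        node_labels = [f"region{i + 1:03d}" for i in range(n_nodes)]
    iu = np.triu_indices(n_nodes, k=1)
    mats = np.zeros((values.shape[0], n_nodes, n_nodes))
    mats[:, iu[0], iu[1]] = values
    mats[:, iu[1], iu[0]] = values
    return ConnectomeSet(subject_ids=subject_ids, node_labels=node_labels,
                         matrices=mats)


def confound_design(covariates: pd.DataFrame,
                    columns=("age", "sex", "scanner")) -> pd.DataFrame:
    """Design matrix: intercept + age + sex + one-hot scanner (reference
    level dropped) + every GAF column, in a fixed order."""
    parts = {"intercept": np.ones(len(covariates))}
    if "age" in covariates:
        parts["age"] = covariates["age"].to_numpy(float)
    if "sex" in covariates:
        parts["sex"] = covariates["sex"].to_numpy(float)
    if "scanner" in covariates:
        levels = sorted(covariates["scanner"].astype(str).unique())
        for lev in levels[1:]:  # first level is the reference
            parts[f"scanner[{lev}]"] = (
                covariates["scanner"].astype(str) == lev).to_numpy(float)
    for col in covariates.columns:
        if col.startswith("gaf"):
            parts[col] = covariates[col].to_numpy(float)
    return pd.DataFrame(parts, index=covariates.index)


def _check_full_rank(D: pd.DataFrame) -> None:
    A = D.to_numpy(float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name the offending columns via pivoted QR
        _, _, piv = scipy.linalg.qr(A, pivoting=True, mode="economic")
        bad = [D.columns[k] for k in piv[rank:]]
        raise ValueError(f"confound design is rank-deficient; "
                         f"collinear columns: {bad}")


def adjust_confounds(X, covariates: pd.DataFrame,
                     design: pd.DataFrame | None = None):
    """Per-feature OLS residuals of X on the confound design.

    Residual columns have zero mean and zero sample correlation with
    every covariate column (within numerical precision); the operation is
    idempotent and commutes with column scaling.
    """
    if design is None:
        design = confound_design(covariates)
    if len(design) != len(X):
        raise ValueError("covariate rows do not align with data rows")
    _check_full_rank(design)
    A = design.to_numpy(float)
    values = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(
        X, float)
    if not np.isfinite(values).all():
        raise ValueError("adjust_confounds requires complete data")
    # residuals via orthonormal basis of the design column space
    Q, _ = np.linalg.qr(A)
    resid = values - Q @ (Q.T @ values)
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(resid, index=X.index, columns=X.columns)
    return resid


def filter_behaviors(behaviors: BehaviorTable) -> BehaviorTable:
    """Keep variables with more than ten observations; dichotomous
    variables additionally need their minority level to cover at least 5%
    of non-missing observations."""
    keep = []
    for var in behaviors.values.columns:
        obs = behaviors.values[var].dropna()
        if len(obs) <= 10:
            logger.info("dropping %s: only %d observations", var, len(obs))
            continue
        if behaviors.types[var] == "dichotomous":
            counts = obs.value_counts()
            if len(counts) < 2 or counts.min() / len(obs) < 0.05:
                logger.info("dropping %s: minority level below 5%%", var)
                continue
        keep.append(var)
    return behaviors.subset(keep)


def adjust_behaviors(behaviors: BehaviorTable,
                     covariates: pd.DataFrame) -> pd.DataFrame:
    """Age/sex-adjust each behavior on its non-missing rows.

    Continuous: OLS residuals.  Dichotomous: response residuals
    ``y - p_hat`` from logistic regression; on non-convergence or perfect
    separation the fit falls back to linear-probability-model residuals
    with a warning.  Missing rows stay missing.
    """
    out = pd.DataFrame(np.nan, index=behaviors.values.index,
                       columns=behaviors.values.columns)
    base = pd.DataFrame({
        "intercept": 1.0,
        "age": covariates["age"].to_numpy(float),
        "sex": covariates["sex"].to_numpy(float),
    }, index=covariates.index)
    for var in behaviors.values.columns:
        y = behaviors.values[var]
        mask = y.notna()
        if mask.sum() < 3:
            logger.warning("skipping %s: fewer than 3 observations", var)
            continue
        D = base.loc[mask.values].to_numpy(float)
        yv = y[mask.values].to_numpy(float)
        if behaviors.types[var] == "continuous":
            beta, *_ = np.linalg.lstsq(D, yv, rcond=None)
            out.loc[mask.values, var] = yv - D @ beta
        else:
            levels = np.sort(np.unique(yv))
            y01 = (yv == levels[-1]).astype(float)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(y01, D).fit(disp=0, maxiter=100)
                if not fit.mle_retvals.get("converged", True):
                    raise np.linalg.LinAlgError("logit did not converge")
                out.loc[mask.values, var] = y01 - fit.predict(D)
            except Exception:  # separation / convergence failure
                logger.warning(
                    "logistic fit failed for %s; using linear-probability "
                    "residuals", var)
                beta, *_ = np.linalg.lstsq(D, y01, rcond=None)
                out.loc[mask.values, var] = y01 - D @ beta
    return out
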