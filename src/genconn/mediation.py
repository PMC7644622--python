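"""Behavior correlations, the permutation combined probability test, and
mediation of genetic risk through the connectome.

Adjusted behavior variables are correlated with the connectomic canonical
score; one-tailed p-values (H1: r > 0, since higher values encode higher
vulnerability) enter Fisher's statistic T = -2 sum ln p, whose null is
built by permuting the score and recomputing the full p-set — this keeps
the dependence between behavior variables intact, which a parametric
chi-square combination would not.

Mediation uses the product-of-coefficients estimator: with the genetic
canonical score x, connectomic canonical score m and behavior y,
a is the OLS slope of m ~ x and (b, c') come from y ~ x + m; the indirect
effect is a*b with Sobel standard error sqrt(a^2 SE_b^2 + b^2 SE_a^2).
For continuous y the OLS identity total = c' + a*b holds exactly.  The
mediation null permutes the mediator, breaking both the a and b paths
while preserving the x-y relation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CombinedTestResult:
    per_variable: pd.DataFrame     # columns: statistic-specific, incl. p
    T: float
    B: int
    p: float


@dataclass
class MediationRow:
    a: float
    b: float
    cprime: float
    indirect: float
    se: float
    p_one_tailed: float


def behavior_correlations(conn_score, behaviors: pd.DataFrame
                          ) -> pd.DataFrame:
    """Pearson r and one-tailed p (H1: r > 0) between the connectomic
    canonical score and each adjusted behavior, on pairwise-complete
    rows.  Variables with fewer than 3 complete pairs are skipped."""
    score = np.asarray(conn_score, float)
    rows = []
    for var in behaviors.columns:
        y = behaviors[var].to_numpy(float)
        mask = np.isfinite(y) & np.isfinite(score)
        if mask.sum() < 3:
            logger.warning("skipping %s: <3 complete pairs", var)
            continue
        if np.std(y[mask]) == 0 or np.std(score[mask]) == 0:
            logger.warning("skipping %s: zero variance", var)
            continue
        res = stats.pearsonr(score[mask], y[mask], alternative="greater")
        rows.append((var, res.statistic, res.pvalue, int(mask.sum())))
    return pd.DataFrame(rows, columns=["variable", "r", "p", "n"])


def _fisher_T(pvals: np.ndarray, floor: float) -> float:
    p = np.clip(np.asarray(pvals, float), floor, 1.0)
    return float(-2.0 * np.sum(np.log(p)))


def combined_probability_test(pvals, recompute_fn, B: int = 1000,
                              seed: int | None = 0) -> CombinedTestResult:
    """Permutation-based combination of dependent one-tailed p-values.

    ``recompute_fn(rng)`` must return the full set of one-tailed p-values
    for one permuted dataset (the caller owns the permutation scheme so
    inter-variable dependence is preserved).  Combined
    p = (1 + #{T_b >= T_obs}) / (B + 1).  Zero p-values are clamped to
    1/(B+1) with a warning.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    pvals = np.asarray(pvals, float)
    floor = 1.0 / (B + 1)
    if (pvals <= 0).any():
        warnings.warn("zero p-values clamped to 1/(B+1)", stacklevel=2)
    T_obs = _fisher_T(pvals, floor)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(B):
        p_b = recompute_fn(rng)
        if _fisher_T(p_b, floor) >= T_obs - 1e-12:
            exceed += 1
    p_comb = (1 + exceed) / (B + 1)
    per_var = pd.DataFrame({"p": pvals})
    return CombinedTestResult(per_variable=per_var, T=T_obs, B=B, p=p_comb)


def combined_behavior_test(conn_score, behaviors: pd.DataFrame,
                           B: int = 1000, seed: int | None = 0
                           ) -> CombinedTestResult:
    """Combined probability test over all behavior-score correlations,
    with the null built by shuffling the connectomic score."""
    obs = behavior_correlations(conn_score, behaviors)
    if obs.empty:
        raise ValueError("no usable behavior variables")
    score = np.asarray(conn_score, float)
    used = behaviors[obs["variable"]]

    def recompute(rng):
        perm = score[rng.permutation(len(score))]
        return behavior_correlations(perm, used)["p"].to_numpy()

    result = combined_probability_test(obs["p"].to_numpy(), recompute,
                                       B=B, seed=seed)
    result.per_variable = obs
    return result


def _ols(y: np.ndarray, X: np.ndarray):
    """OLS with intercept prepended; returns (coefs, SEs) excluding the
    intercept."""
    n = len(y)
    D = np.hstack([np.ones((n, 1)), X])
    beta, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    df = n - D.shape[1]
    sigma2 = resid @ resid / df
    try:
        cov = sigma2 * np.linalg.inv(D.T @ D)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "mediation design is collinear (x and m may be identical)"
        ) from exc
    se = np.sqrt(np.diag(cov))
    return beta[1:], se[1:]


def mediate(x, m, y) -> MediationRow:
    """Single-mediator analysis on complete cases.

    a from m ~ x; (c', b) from y ~ x + m; indirect = a*b with Sobel SE
    and a one-tailed p for indirect > 0 (positive mediation of risk)."""
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    mask = np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
    x, m, y = x[mask], m[mask], y[mask]
    for name, v in (("x", x), ("m", m), ("y", y)):
        if np.std(v) == 0:
            raise ValueError(f"zero variance in {name}")
    (a,), (se_a,) = _ols(m, x[:, None])
    (cprime, b), (_, se_b) = _ols(y, np.column_stack([x, m]))
    indirect = a * b
    se = np.sqrt(a ** 2 * se_b ** 2 + b ** 2 * se_a ** 2)
    z = indirect / se if se > 0 else np.inf * np.sign(indirect)
    p = float(stats.norm.sf(z))
    return MediationRow(a=float(a), b=float(b), cprime=float(cprime),
                        indirect=float(indirect), se=float(se),
                        p_one_tailed=p)


def mediation_table(gen_score, conn_score, behaviors: pd.DataFrame
                    ) -> pd.DataFrame:
    """Per-variable mediation of the genetic score on each behavior
    through the connectomic score."""
    rows = []
    for var in behaviors.columns:
        try:
            r = mediate(gen_score, conn_score, behaviors[var])
        except ValueError:
            logger.warning("mediation skipped for %s", var)
            continue
        rows.append((var, r.a, r.b, r.cprime, r.indirect, r.se,
                     r.p_one_tailed))
    return pd.DataFrame(rows, columns=["variable", "a", "b", "cprime",
                                       "indirect", "se", "p"])


def combined_mediation_test(gen_score, conn_score, behaviors: pd.DataFrame,
                            B: int = 1000, seed: int | None = 0
                            ) -> CombinedTestResult:
    """Combined probability test over per-variable indirect-effect
    p-values.  The null shuffles the mediator rows jointly against the
    (x, y) pairs, breaking both legs of the indirect path while leaving
    the x-y relation untouched."""
    obs = mediation_table(gen_score, conn_score, behaviors)
    if obs.empty:
        raise ValueError("no usable behavior variables for mediation")
    mvec = np.asarray(conn_score, float)
    used = behaviors[obs["variable"]]

    def recompute(rng):
        mp = mvec[rng.permutation(len(mvec))]
        return mediation_table(gen_score, mp, used)["p"].to_numpy()

    result = combined_probability_test(obs["p"].to_numpy(), recompute,
                                       B=B, seed=seed)
    result.per_variable = obs
    return result
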