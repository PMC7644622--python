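"""Max-statistic permutation inference for CCA modes and strengths.

Mode significance: the subject rows of one block are randomly permuted
relative to the other, CCA is refit, and the maximum canonical
correlation (in absolute value) is recorded; comparing each observed
mode's r against this null controls the family-wise error across modes.
P-values use the add-one convention p = (1 + #exceedances) / (B + 1), so
the smallest attainable p is 1/(B+1) — e.g. p < 1e-4 at B = 10,000.

Canonical strengths (feature-score correlations) are recomputed for
mode 1 of every permuted fit; per-feature exceedance counters stream so
memory stays O(features), and the per-permutation mean squared
correlation doubles as the null for the variance-explained ratio.

Grouped BH-FDR: all connection strengths form one group; genetic
strengths are corrected within each phenotype.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import PermutationNull

logger = logging.getLogger(__name__)

_CHUNK = 128  # permutations processed per batch


def _center_orthonormal(M: np.ndarray) -> np.ndarray:
    Mc = M - M.mean(axis=0)
    Q, _ = np.linalg.qr(Mc)
    return Q


def _unit_columns(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    safe = np.where(norms == 0, 1.0, norms)
    Z = Xc / safe
    Z[:, norms == 0] = np.nan
    return Z


def permutation_test_modes(
    U, V, B: int = 10_000, seed: int | None = 0,
    X_x=None, X_y=None,
    strengths_x: np.ndarray | None = None,
    strengths_y: np.ndarray | None = None,
    perms=None,
) -> tuple[np.ndarray, PermutationNull]:
    """Permutation p-values for every CCA mode of (U, V).

    Rows of ``V`` are permuted while ``U`` stays fixed (the PCA bases are
    those of the unpermuted data; a permutation only breaks the subject
    alignment).  Returns (per-mode p-values, PermutationNull).

    When the original feature blocks ``X_x`` / ``X_y`` and the observed
    mode-1 strengths are supplied, per-feature exceedance counters for
    the permuted mode-1 strengths and per-permutation variance-explained
    values are accumulated as well.

    ``perms`` may supply explicit permutations (iterable of index
    arrays) — e.g. the full enumeration on tiny n — overriding ``B``.
    """
    from .cca import fit_cca  # local import to avoid a cycle

    U = np.asarray(U, float)
    V = np.asarray(V, float)
    n = U.shape[0]
    modes = fit_cca(U, V)
    r_obs = np.array([m.r for m in modes])

    if perms is not None:
        perm_list = [np.asarray(p, int) for p in perms]
        B = len(perm_list)
    else:
        if B < 1:
            raise ValueError("B must be >= 1")
        rng = np.random.default_rng(seed)
        perm_list = None

    Qu = _center_orthonormal(U)
    Qv = _center_orthonormal(V)

    if (X_x is None) != (X_y is None):
        raise ValueError("supply both feature blocks or neither")
    collect = X_x is not None
    if collect:
        if strengths_x is None or strengths_y is None:
            raise ValueError("observed strengths required when feature "
                             "blocks are supplied for streaming")
        Zx = _unit_columns(np.asarray(X_x, float))
        Zy = _unit_columns(np.asarray(X_y, float))
        abs_sx = np.abs(np.asarray(strengths_x, float))
        abs_sy = np.abs(np.asarray(strengths_y, float))
        exceed_x = np.zeros(Zx.shape[1])
        exceed_y = np.zeros(Zy.shape[1])
        varexp_x = np.empty(B)
        varexp_y = np.empty(B)
    else:
        exceed_x = exceed_y = varexp_x = varexp_y = None

    max_abs_r = np.empty(B)
    done = 0
    while done < B:
        nb = min(_CHUNK, B - done)
        if perm_list is not None:
            idx = np.stack(perm_list[done:done + nb])
        else:
            idx = np.stack([rng.permutation(n) for _ in range(nb)])
        Qvp = Qv[idx]                        # (nb, n, K_v)
        M = np.einsum("ni,bnj->bij", Qu, Qvp, optimize=True)
        if collect:
            Wb, sb, Ztb = np.linalg.svd(M)
            max_abs_r[done:done + nb] = sb[:, 0]
            # mode-1 scores of each permuted fit, unit norm, zero mean.
            # within permutation b the y-side score aligned to the
            # (unpermuted) y features is Qv @ z_b: the permutation applied
            # to both score and features cancels in the correlation.
            gs = Qu @ Wb[:, :, 0].T                      # (n, nb)
            cs = Qv @ Ztb[:, 0, :].T                     # (n, nb)
            corr_x = Zx.T @ gs                           # (p_x, nb)
            corr_y = Zy.T @ cs
            exceed_x += (np.abs(corr_x) >= abs_sx[:, None]).sum(axis=1)
            exceed_y += (np.abs(corr_y) >= abs_sy[:, None]).sum(axis=1)
            varexp_x[done:done + nb] = np.nanmean(corr_x ** 2, axis=0)
            varexp_y[done:done + nb] = np.nanmean(corr_y ** 2, axis=0)
        else:
            sb = np.linalg.svd(M, compute_uv=False)
            max_abs_r[done:done + nb] = sb[:, 0]
        done += nb

    # 1e-12 slack counts a permutation reproducing the observed alignment
    # (e.g. the identity under exhaustive enumeration) as a tie regardless
    # of floating-point summation order
    pvals = (1 + np.array([(max_abs_r >= r - 1e-12).sum()
                           for r in r_obs])) / (B + 1)
    null = PermutationNull(B=B, seed=seed, max_abs_r=max_abs_r,
                           strength_exceed_x=exceed_x,
                           strength_exceed_y=exceed_y,
                           varexp_x=varexp_x, varexp_y=varexp_y)
    return pvals, null


def strength_pvalues(observed: np.ndarray, null: PermutationNull,
                     block: str = "y") -> np.ndarray:
    """Per-feature permutation p-values for mode-1 canonical strengths,
    each feature against its own permuted-strength null:
    p_j = (1 + #{b : |rho_jb| >= |rho_j|}) / (B + 1).  Features with
    undefined (NaN) observed strength return NaN (logged)."""
    counters = (null.strength_exceed_x if block == "x"
                else null.strength_exceed_y)
    if counters is None:
        raise ValueError("null does not carry strength exceedance counters")
    observed = np.asarray(observed, float)
    if len(observed) != len(counters):
        raise ValueError("observed strengths do not match null counters")
    p = (1.0 + counters) / (null.B + 1)
    bad = ~np.isfinite(observed)
    if bad.any():
        logger.info("strength_pvalues: %d constant features excluded",
                    int(bad.sum()))
        p = p.copy()
        p[bad] = np.nan
    return p


def bh_fdr(pvals, groups=None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, applied within each group
    independently.  ``groups`` gives one label per p-value (None = a
    single group); NaN p-values propagate as NaN.  Empty groups are
    skipped."""
    p = np.asarray(pvals, float)
    q = np.full_like(p, np.nan)
    if groups is None:
        groups = np.zeros(len(p))
    groups = np.asarray(groups)
    for g in pd.unique(groups):
        mask = (groups == g) & np.isfinite(p)
        if not mask.any():
            continue
        _, qv, _, _ = multipletests(p[mask], method="fdr_bh")
        q[mask] = qv
    return q


def build_strength_table(feature_ids, strengths, pvals, qvals,
                         group_labels) -> pd.DataFrame:
    """Assemble the per-feature strength table (strength, permutation p,
    FDR q, group)."""
    return pd.DataFrame({
        "feature_id": list(feature_ids),
        "strength": np.asarray(strengths, float),
        "p": np.asarray(pvals, float),
        "q": np.asarray(qvals, float),
        "group": list(group_labels),
    })


def null_variance_ratio(observed: float, null: PermutationNull,
                        block: str = "y"):
    """Ratio of the observed variance-explained proportion to the mean of
    its permutation null."""
    from .cca import variance_explained_summary

    values = null.varexp_x if block == "x" else null.varexp_y
    if values is None:
        raise ValueError("null does not carry variance-explained draws")
    return variance_explained_summary(observed, values)
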