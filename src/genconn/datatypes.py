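"""In-memory containers shared across the pipeline stages.

Tabular data live in pandas objects (subjects as rows, indexed by subject
id); dense numerics live in numpy arrays.  The small dataclasses here add
the domain invariants (symmetry, alignment, bounded correlations) that a
bare DataFrame cannot express.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class GenotypeTable:
    """Subjects x SNPs effect-allele dosage matrix plus per-SNP metadata.

    ``dosages`` holds counts in {0, 1, 2} (NaN = missing); ``snp_meta`` is
    indexed by snp_id with columns ``effect_allele``, ``phenotype``,
    ``phenotype_group`` and ``gwas_p``.
    """

    dosages: pd.DataFrame
    snp_meta: pd.DataFrame
    planted: Optional[dict] = None  # generator-internal ground-truth hooks

    def __post_init__(self) -> None:
        missing = [c for c in self.dosages.columns
                   if c not in self.snp_meta.index]
        if missing:
            raise ValueError(f"SNPs without metadata: {missing[:5]}")

    @property
    def subject_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns


@dataclass
class ConnectomeSet:
    """Per-subject symmetric node x node matrices of mean fascicle FA.

    ``matrices`` has shape (n_subjects, n_nodes, n_nodes); diagonals are
    ignored.  Symmetry is validated to 1e-10 at construction.
    """

    subject_ids: list
    node_labels: list
    matrices: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1] != m.shape[2]:
            raise ValueError("matrices must be (subjects, nodes, nodes)")
        if m.shape[0] != len(self.subject_ids):
            raise ValueError("subject_ids do not match matrix count")
        if m.shape[1] != len(self.node_labels):
            raise ValueError("node_labels do not match matrix size")
        self.matrices = m

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.matrices.shape[0]


@dataclass
class BehaviorTable:
    """Behavior battery: values (subjects x variables, NaN = missing),
    per-variable type ('continuous' | 'dichotomous') and vulnerability
    sign (+1 when higher values mean higher psychiatric vulnerability)."""

    values: pd.DataFrame
    types: pd.Series
    vulnerability_sign: pd.Series

    def __post_init__(self) -> None:
        for var in self.values.columns:
            if var not in self.types.index:
                raise ValueError(f"behavior {var!r} has no declared type")
            if self.types[var] not in ("continuous", "dichotomous"):
                raise ValueError(f"unknown behavior type {self.types[var]!r}")
        bad = [v for v in self.values.columns
               if self.types[v] == "dichotomous"
               and self.values[v].dropna().nunique() > 2]
        if bad:
            raise ValueError(f"dichotomous variables with >2 levels: {bad}")

    def subset(self, names) -> "BehaviorTable":
        names = list(names)
        return BehaviorTable(self.values[names], self.types[names],
                             self.vulnerability_sign[names])


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream validation."""

    causal_snp_ids: list
    signal_connection_ids: np.ndarray          # upper-triangle edge indices
    true_genetic_weights: np.ndarray           # on causal SNPs, unit norm
    true_connection_effects: np.ndarray        # per signal edge
    latent_g: np.ndarray
    latent_m: np.ndarray
    rho: float
    behavior_paths: dict = field(default_factory=dict)  # name -> (a, b, cprime)


@dataclass
class SummaryStats:
    """GWAS summary statistics: one row per SNP (id, effect_allele, beta, p)."""

    table: pd.DataFrame
    phenotype: str = "synthetic"

    def __post_init__(self) -> None:
        required = {"snp_id", "effect_allele", "beta", "p"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"summary stats missing columns: {sorted(missing)}")
        if self.table["snp_id"].duplicated().any():
            raise ValueError("duplicate SNP ids in summary statistics")
        if (self.table["p"] <= 0).any():
            raise ValueError("summary-stat p-values must be > 0")


@dataclass
class PCAReduction:
    """Column-centered PCA of one data block."""

    loadings: np.ndarray           # features x components, orthonormal cols
    scores: np.ndarray             # subjects x components
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: Optional[np.ndarray] = None  # set when features were z-scored

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xc = np.asarray(X, float) - self.mean
        if self.scale is not None:
            Xc = Xc / self.scale
        return Xc @ self.loadings


@dataclass
class CCAMode:
    """One mode of covariation between the genetic (x) and connectomic (y)
    blocks: canonical correlation r, weights on the PC scores, and
    unit-variance per-subject canonical scores."""

    index: int
    r: float
    x_weights: np.ndarray
    y_weights: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    flipped: bool = False

    def flip(self) -> "CCAMode":
        return CCAMode(self.index, self.r, -self.x_weights, -self.y_weights,
                       -self.x_scores, -self.y_scores, not self.flipped)


@dataclass
class PermutationNull:
    """Null distributions from the max-|r| permutation scheme."""

    B: int
    seed: Optional[int]
    max_abs_r: np.ndarray                       # (B,)
    strength_exceed_x: Optional[np.ndarray] = None  # per-feature counters
    strength_exceed_y: Optional[np.ndarray] = None
    varexp_x: Optional[np.ndarray] = None       # (B,) mean squared corr
    varexp_y: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.max_abs_r) != self.B:
            raise ValueError("null must hold exactly B max-|r| draws")
        if np.any((self.max_abs_r < 0) | (self.max_abs_r > 1 + 1e-12)):
            raise ValueError("max |r| draws must lie in [0, 1]")


@dataclass
class VarianceExplained:
    """Mean squared feature-score correlation, against its permutation null."""

    observed: float
    null_mean: float
    ratio: float
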