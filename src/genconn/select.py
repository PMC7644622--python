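"""Selection of analysis SNPs from a GWAS-catalog-like table.

SNPs associated with a phenotype of interest at genome-wide significance
(p < 5e-8) enter the analysis when genotyped; a significant SNP absent
from the genotype data is replaced by its best genotyped LD proxy with
r2 strictly above 0.8.  Both thresholds are strict inequalities.
"""

from __future__ import annotations

import pandas as pd

CATALOG_COLUMNS = ["snp_id", "phenotype", "phenotype_group", "gwas_p"]
PROXY_COLUMNS = ["index_snp_id", "proxy_snp_id", "r_squared"]

PHENOTYPE_GROUPS = {"psychiatric", "neurological", "behavior-cognition",
                    "brain-morphology-function", "control"}


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    missing = set(CATALOG_COLUMNS) - set(catalog.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    if (catalog["gwas_p"] <= 0).any():
        raise ValueError("catalog gwas_p must be > 0")
    if catalog["snp_id"].eq("").any():
        raise ValueError("catalog contains empty snp_id")
    dup = catalog.duplicated(subset=["snp_id", "phenotype"])
    if dup.any():
        raise ValueError("catalog has duplicate (snp_id, phenotype) rows")
    return catalog


def validate_proxies(proxies: pd.DataFrame) -> pd.DataFrame:
    missing = set(PROXY_COLUMNS) - set(proxies.columns)
    if missing:
        raise ValueError(f"proxy table missing columns: {sorted(missing)}")
    if ((proxies["r_squared"] < 0) | (proxies["r_squared"] > 1)).any():
        raise ValueError("proxy r_squared must lie in [0, 1]")
    if (proxies["index_snp_id"] == proxies["proxy_snp_id"]).any():
        raise ValueError("a SNP cannot proxy itself")
    return proxies


def select_snps(
    catalog: pd.DataFrame,
    genotyped_ids,
    proxies: pd.DataFrame | None = None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.8,
) -> pd.DataFrame:
    """Select analysis SNPs with provenance.

    Returns a long-format DataFrame (one row per selected SNP x phenotype
    annotation) with columns ``snp_id``, ``phenotype``, ``phenotype_group``,
    ``gwas_p``, ``provenance`` ('direct' or 'proxy-of-<index snp>') and
    ``r_squared`` (NaN for direct hits).  A SNP significant for several
    phenotypes appears once per annotation but only once in the
    deduplicated dosage matrix (``result['snp_id'].unique()``).

    Rules: strict p < p_threshold; for a significant SNP not genotyped,
    the genotyped proxy with the highest r_squared strictly above
    r2_threshold is substituted (ties broken by lexicographic proxy id).
    Output ordering is deterministic and invariant to input row order.
    """
    if not (0 < p_threshold < 1) or not (0 < r2_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1) (r2 may equal 1)")
    catalog = validate_catalog(catalog)
    genotyped = set(genotyped_ids)
    significant = catalog[catalog["gwas_p"] < p_threshold]
    if significant.empty:
        return pd.DataFrame(columns=CATALOG_COLUMNS
                            + ["provenance", "r_squared"])

    best_proxy: dict[str, tuple[str, float]] = {}
    if proxies is not None and len(proxies):
        proxies = validate_proxies(proxies)
        usable = proxies[(proxies["r_squared"] > r2_threshold)
                         & proxies["proxy_snp_id"].isin(genotyped)]
        for index_id, grp in usable.groupby("index_snp_id"):
            # highest r2 wins; lexicographically smallest id breaks ties
            grp = grp.sort_values(["r_squared", "proxy_snp_id"],
                                  ascending=[False, True])
            row = grp.iloc[0]
            best_proxy[index_id] = (row["proxy_snp_id"],
                                    float(row["r_squared"]))

    rows = []
    for rec in significant.itertuples(index=False):
        if rec.snp_id in genotyped:
            rows.append((rec.snp_id, rec.phenotype, rec.phenotype_group,
                         rec.gwas_p, "direct", float("nan")))
        elif rec.snp_id in best_proxy:
            proxy_id, r2 = best_proxy[rec.snp_id]
            rows.append((proxy_id, rec.phenotype, rec.phenotype_group,
                         rec.gwas_p, f"proxy-of-{rec.snp_id}", r2))
    result = pd.DataFrame(rows, columns=CATALOG_COLUMNS
                          + ["provenance", "r_squared"])
    result = result.drop_duplicates(
        subset=["snp_id", "phenotype", "provenance"])
    return (result.sort_values(["snp_id", "phenotype", "provenance"])
            .reset_index(drop=True))
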