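"""Discover the genome-connectome mode and calibrate its significance.

Pipeline: vectorize connectomes -> adjust for age/sex/scanner/ancestry ->
PCA both blocks -> CCA -> max-|r| permutation test -> canonical strengths
with grouped BH-FDR.
"""

import numpy as np

import genconn as g

cfg = g.SimulationConfig(
    n_subjects=500, n_snps=500, n_nodes=60, n_causal_snps=50,
    n_signal_connections=100, rho=0.7, seed=1)
genotypes, connectomes, covariates, _, _, truth = g.simulate_cohort(cfg)

conn_vec, edge_idx = g.vectorize(connectomes)
res = g.run_cca_pipeline(genotypes.dosages, conn_vec, covariates,
                         n_components=20)

mode_p, null = g.permutation_test_modes(
    res.gen_scores_pca, res.conn_scores_pca, B=999, seed=2,
    X_x=res.gen_block, X_y=res.conn_block,
    strengths_x=res.gen_strengths, strengths_y=res.conn_strengths)

q = g.bh_fdr(g.strength_pvalues(res.conn_strengths, null, block="y"))
called = np.flatnonzero(q < 0.05)
signal = set(truth.signal_connection_ids.tolist())
recall = len(signal & set(called.tolist())) / len(signal)

print(f"mode 1 canonical correlation r = {res.mode.r:.3f} "
      f"(planted rho = {truth.rho})")
print(f"permutation p = {mode_p[0]:.4g}  (null mean max |r| = "
      f"{null.max_abs_r.mean():.3f})")
print(f"second mode p = {mode_p[1]:.3f} (expected non-significant)")
print(f"connections with FDR q < 0.05: {len(called)}; "
      f"planted-edge recall = {recall:.2f}")
# r approximates the planted rho; the permutation p controls family-wise
# error over all modes, and FDR-significant strengths recover the planted
# network with few false edges.
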