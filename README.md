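# genconn

Joint analysis of psychiatric-risk SNPs and structural brain
connectomes: a permutation-calibrated CCA that discovers modes of
genome–connectome covariation, with downstream polygenic-score,
behavior, mediation and robustness analyses.

## The problem

Many psychiatric disorders share genetic risk and show overlapping brain
findings, but case–control imaging studies cannot separate vulnerability
from consequences of illness.  One way forward is to ask, in *healthy*
subjects, whether established risk variants covary with white-matter
connectivity: given a subjects × SNPs matrix **X**<sub>g</sub> of
effect-allele dosages (SNPs at genome-wide significance, p < 5×10⁻⁸,
with LD proxies at r² > 0.8 for ungenotyped hits) and a subjects ×
connections matrix **X**<sub>c</sub> of mean fascicle fractional
anisotropy (a symmetric n×n parcellation vectorized to n(n−1)/2 edges;
120 regions → 7140 connections), the analysis seeks paired weight
vectors (a, b) maximizing

    r = corr(U a, V b)

where U, V are the 100-PC reductions of **X**<sub>g</sub> and the
confound-adjusted **X**<sub>c</sub> (residualized on age, sex, scanner,
and genetic ancestry factors).  Each CCA solution is a *mode of
covariation*; per-subject values U a and V b are the genetic and
connectomic *canonical scores*, and feature–score correlations are
*canonical strengths*.  Because CCA overfits by construction, mode
significance comes from a max-|r| permutation test (subject rows of one
block shuffled, CCA refit, maximum |r| recorded — family-wise-error
controlled across modes), strengths get per-feature permutation p-values
with grouped Benjamini–Hochberg FDR, and effect size is the ratio of
variance explained by the mode to its permutation-null mean.

Downstream, the connectomic score is related to clumping+thresholding
polygenic risk scores (ΔR² beyond ancestry covariates, threshold scan
corrected by permutation), to behavior variables (one-tailed
correlations combined by a permutation Fisher test that tolerates
dependence), and to mediation models testing whether the brain network
transmits genetic risk to behavior (indirect effect a·b with Sobel SE).
A robustness battery reruns the identical pipeline on half-samples,
different PC counts, SNP subsets and subject exclusions.

Raw cohort data of this kind are controlled-access, so the package
ships a first-class synthetic-cohort generator that plants a mode of
known canonical correlation ρ, known signal edges, confound effects and
partially-mediated behaviors — every stage is testable against ground
truth.  See `docs/methods.md` for the full model and its assumptions.

## Worked example

```python
import genconn as g

cfg = g.SimulationConfig(n_subjects=500, n_snps=500, n_nodes=60,
                         n_causal_snps=50, n_signal_connections=100,
                         rho=0.7, seed=1)
genotypes, connectomes, covariates, behaviors, sumstats, truth = \
    g.simulate_cohort(cfg)

conn_vec, edge_idx = g.vectorize(connectomes)
res = g.run_cca_pipeline(genotypes.dosages, conn_vec, covariates,
                         n_components=20)
mode_p, null = g.permutation_test_modes(
    res.gen_scores_pca, res.conn_scores_pca, B=999, seed=2,
    X_x=res.gen_block, X_y=res.conn_block,
    strengths_x=res.gen_strengths, strengths_y=res.conn_strengths)
print(res.mode.r, mode_p[0])
```

Running `python examples/02_discover_mode.py` (this pipeline end to
end) prints:

```
mode 1 canonical correlation r = 0.718 (planted rho = 0.7)
permutation p = 0.001  (null mean max |r| = 0.369)
second mode p = 0.813 (expected non-significant)
connections with FDR q < 0.05: 87; planted-edge recall = 0.87
```

The recovered r ≈ 0.72 tracks the planted ρ = 0.7; the permutation p
sits at its floor 1/(B+1) while the null mean shows what CCA finds in
shuffled data; only the first mode is significant; and the
FDR-significant connections recover 87% of the planted network with no
false edges in this run.  `examples/` has one script per capability
(simulation, mode discovery, PRS, behavior + mediation, robustness).

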