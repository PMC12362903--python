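# qtlblup

Genomic prediction with known causal variants: how much does it help to
genotype the QTL themselves?

`qtlblup` is for quantitative geneticists and animal breeders who want to
study — by simulation, with the truth known — how incorporating causal-variant
(QTL) genotypes changes the accuracy and dispersion bias of genomic
prediction. It simulates a selected livestock population with a fully
additive trait, then compares five predictors of true breeding values (TBV):

- **GBLUP** — one genomic effect; `y = 1μ + Zu + e`, `u ~ N(0, G σ²_u)` with
  the VanRaden relationship matrix `G = WW′ / 2Σ p_j(1−p_j)`,
  `w_ij = x_ij − 2p_j`, built from SNPs plus any included QTL.
- **2GBLUP** — two genomic effects, `y = 1μ + Zu₁ + Zu₂ + e`, separating the
  included QTL (G₁) from the SNPs (G₂), so the QTL signal is not diluted
  among thousands of equally weighted markers.
- **w2GBLUP** — 2GBLUP with per-QTL variance weights `2p_j q_j α_j²` on the
  diagonal of D in `G₁ = WDW′ / 2Σ p_j q_j`.
- **RF / SVR** — random forest and RBF-kernel support vector regression on
  raw 0/1/2 dosages, evaluated exactly like the mixed models.

QTL enter the models in *scenarios*: ranked by the variance they explain
(`2pqα²`), scenario QTLx includes the smallest top set reaching x% of the
genetic variance (QTL0 = SNPs only). Accuracy is `cor(GEBV, TBV)` in a test
generation; dispersion bias is the regression slope of TBV on GEBV. Variance
components are estimated with the package's own average-information REML
(EM-safeguarded, active-set handling at the zero boundary), and marker
effects can be backsolved from any fit.

The simulator covers the whole study design: a long random-mating historic
phase with a bottleneck (plus recurrent marker mutation) that produces
linkage disequilibrium and a U-shaped allele-frequency spectrum; gamma(0.42)
QTL effects scaled to h² = 0.25; and 20 generations of truncation selection
(20 sires × 5,000 dams by default) on a pseudo-EBV with accuracy 0.8,
yielding 12,500 training animals (generations 11–15, phenotyped) and 500
test animals per generation 16–20.

## Worked example

Fit a two-component model at the QTL80 scenario on the scaled-down preset
(5 chromosomes, 600 training animals — the full design is a multi-hour job):

```python
import numpy as np
import qtlblup as q

cfg = q.SimulationConfig.mini_ci()
study = q.simulate_study(cfg, seed=42)

ranking = q.rank_qtl(study.arch, study.p0)
qtl80 = q.build_scenario(ranking, 0.80)
print(f"{qtl80.label}: {qtl80.n_qtl} QTL explain "
      f"{qtl80.achieved_proportion:.1%} of the genetic variance")

ds = study.datasets
X = np.concatenate([ds.train.X, ds.tests[16].X])
from qtlblup.scenarios import assemble_features
fs = assemble_features(X, study.seg_snp, qtl80, "split")
model = q.GenomicMixedModel(
    ds.train.y,
    {"qtl": q.vanraden_g(fs.qtl), "snp": q.vanraden_g(fs.snp)},
    train_index=np.arange(ds.train.n),
)
res = model.fit()
print(res.summary())
pred = res.gebv[ds.train.n:]
print(f"accuracy (gen 16):        {q.accuracy(pred, ds.tests[16].tbv):.3f}")
print(f"dispersion bias (gen 16): {q.dispersion_bias(pred, ds.tests[16].tbv):.3f}")
```

Output:

```
QTL80: 17 QTL explain 80.8% of the genetic variance
Genomic mixed model (REML)
==============================================
n obs:    600    components: 2
log-likelihood (restricted): -662.7204
iterations: 30    converged: True
----------------------------------------------
component           variance     std err
qtl                  0.22160     0.13342
snp                  0.26820     0.13864
residual             3.02214     0.19964
----------------------------------------------
total genetic: 0.48980    h2: 0.1395
accuracy (gen 16):        0.628
dispersion bias (gen 16): 0.645
```

Reading this: 17 QTL carry 80% of the genetic variance (the gamma(0.42)
effect distribution is extremely heavy-tailed), and giving them their own
variance component captures nearly half of the total genetic variance
(σ²_qtl = 0.22 of 0.49). The estimated h² in the training generations is
below the simulated 0.25 because selection has already eroded genetic
variance (Bulmer effect); on unselected generation-0 data the same REML
machinery recovers h² ≈ 0.25. The accuracy of 0.63 beats a plain GBLUP fit
of the same data (0.49), the core result of the study design; the slope of
0.65 (< 1) says these small-sample GEBVs are overdispersed.

The same experiment, replicated end to end with all models and scenarios:

```bash
qtlblup run --preset mini_ci --seed 7 --replicates 10 \
        --scenarios 0,0.8,1.0 --outdir out/
qtlblup summarize out/results.csv
```

which writes per-replicate results, a summary table (means ± SD by scenario ×
model × generation) and a JSON manifest with seeds and file checksums.
`--preset full_scale` runs the full-scale design (hours, ~10 GB peak).

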